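"""Sampling-effort scaling of regression-ready site-level variables.

Stability and asynchrony are coefficient-of-variation statistics, so
dividing abundances by a constant site-level sampled area cannot change
them; sampling effort is instead controlled by an offset.  Responses, the
offset (log total sampled area) and predictors are standardised to
z-scores over the full dataset; the scaled response is z(response) -
z(offset).  The equivalent log-response-ratio route (log response minus
log area, then z-scored) is provided for comparison.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["zscore", "standardize_with_offset", "log_response_ratio"]


def zscore(x: pd.Series) -> pd.Series:
    """z-score; a zero-variance column maps to all-zeros (no adjustment)."""
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        return pd.Series(np.zeros(len(x)), index=x.index, name=x.name)
    return (x - x.mean()) / sd


def _log_or_flag(x: pd.Series) -> pd.Series:
    out = pd.Series(np.where(x > 0, np.log(np.where(x > 0, x, 1.0)), np.nan), index=x.index)
    return out


def standardize_with_offset(
    raw: pd.DataFrame,
    responses: list[str],
    offset: str = "sampled_area",
    predictors: list[str] | None = None,
    log_predictors: list[str] | None = None,
) -> pd.DataFrame:
    """Offset-standardised design table.

    Responses and the offset are log-transformed then z-scored; each scaled
    response column ``<name>_scaled`` is z(log response) - z(log offset).
    Predictors are z-scored (those in ``log_predictors``, e.g. remoteness,
    log-transformed first).  Non-positive values where a log is required
    become missing (flagged as NaN).
    """
    out = raw.copy()
    z_off = zscore(_log_or_flag(raw[offset]))
    out[f"z_log_{offset}"] = z_off
    for col in responses:
        z_resp = zscore(_log_or_flag(raw[col]))
        out[f"z_log_{col}"] = z_resp
        out[f"{col}_scaled"] = z_resp - z_off
    for col in predictors or []:
        base = _log_or_flag(raw[col]) if col in (log_predictors or []) else raw[col]
        out[f"z_{col}"] = zscore(base)
    return out


def log_response_ratio(
    raw: pd.DataFrame,
    responses: list[str],
    offset: str = "sampled_area",
    predictors: list[str] | None = None,
    log_predictors: list[str] | None = None,
) -> pd.DataFrame:
    """Log-response-ratio design table: log(response/area), z-scored."""
    out = raw.copy()
    log_off = _log_or_flag(raw[offset])
    for col in responses:
        ratio = _log_or_flag(raw[col]) - log_off
        out[f"{col}_lrr"] = ratio
        out[f"{col}_scaled"] = zscore(ratio)
    for col in predictors or []:
        base = _log_or_flag(raw[col]) if col in (log_predictors or []) else raw[col]
        out[f"z_{col}"] = zscore(base)
    return out
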