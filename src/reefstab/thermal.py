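"""Species Temperature Index (STI) and thermal-sensitivity classification.

A species' STI is the 95th percentile of the pruned distribution of
long-term mean SSTs at its occurrence locations (upper realized thermal
niche).  Each site gets a thermal threshold from the hottest conditions
reached during marine heatwaves over its sampling period; species with
STI at or above the threshold are thermally resistant, the rest sensitive.
Abundances summed per thermal class and trophic category feed downstream
smooth-model fitting of thermal sensitivity trends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mhw import Climatology, MHWEvent, day_of_year_366

__all__ = [
    "compute_sti",
    "site_thermal_threshold",
    "classify_thermal",
    "thermal_abundance_table",
]

MIN_RECORDS = 10


def compute_sti(
    temperatures, min_records: int = MIN_RECORDS, prune: tuple[float, float] = (5.0, 95.0)
) -> float:
    """STI = 95th percentile of the pruned occurrence-temperature distribution.

    Values strictly below the lower and strictly above the upper percentile
    of the raw distribution are discarded as outliers first; percentiles use
    the linear-interpolation convention.  NaN when fewer than ``min_records``
    records are available.
    """
    t = np.asarray(temperatures, dtype=float)
    t = t[~np.isnan(t)]
    if len(t) < min_records:
        return float("nan")
    lo, hi = np.percentile(t, prune)
    kept = t[(t >= lo) & (t <= hi)]
    return float(np.percentile(kept, 95.0))


def site_thermal_threshold(
    events: list[MHWEvent],
    clim: Climatology,
    survey_years: set[int],
    convention: str = "sst",
) -> tuple[float, set[str]]:
    """Site thermal threshold from maximum heatwave intensity while surveyed.

    convention="sst" (default): the hottest SST attained during heatwave
    days within survey years, i.e. max over event days of
    (climatological threshold + daily intensity) — on the same degC scale as
    STI.  convention="anomaly": the bare maximum intensity anomaly instead.
    With no heatwave during the sampling period the fallback is the maximum
    climatological threshold over the survey days, flagged "no-events".
    """
    if convention not in ("sst", "anomaly"):
        raise ValueError("convention must be 'sst' or 'anomaly'")
    survey_years = set(int(y) for y in survey_years)
    if clim.clim_threshold is None or np.all(np.isnan(clim.clim_threshold)):
        raise ValueError("climatology missing")
    best = -np.inf
    for ev in events:
        inside = np.asarray([d.year in survey_years for d in ev.daily_dates])
        if not inside.any():
            continue
        intens = ev.daily_intensity[inside]
        if convention == "anomaly":
            best = max(best, float(intens.max()))
        else:
            thr = clim.clim_threshold[day_of_year_366(ev.daily_dates[inside]) - 1]
            best = max(best, float((thr + intens).max()))
    if np.isfinite(best):
        return best, set()
    fallback = float(np.nanmax(clim.clim_threshold))
    return (fallback if convention == "sst" else 0.0), {"no-events"}


def classify_thermal(sti: float, threshold: float) -> str:
    """"resistant" iff STI >= threshold, else "sensitive"."""
    if np.isnan(sti) or np.isnan(threshold):
        raise ValueError("STI and threshold must both be defined")
    return "resistant" if sti >= threshold else "sensitive"


@dataclass
class ThermalTableReport:
    n_excluded_no_category: int
    n_excluded_no_sti: int


def thermal_abundance_table(
    survey: pd.DataFrame,
    sti: pd.Series,
    site_thresholds: pd.Series,
    traits: pd.DataFrame,
) -> tuple[pd.DataFrame, ThermalTableReport]:
    """Sum abundance per site x year x thermal class x trophic category.

    ``sti`` maps species_id -> STI; ``site_thresholds`` maps site_id ->
    threshold degC; ``traits`` must carry species_id and trophic_category.
    Species lacking a trophic category or STI are excluded (counted in the
    report); class-category combinations absent from a site are simply
    absent, not zero-filled.  log1p-transformed and z-scored abundance
    columns are appended for smooth-model fitting.
    """
    cat = traits.set_index("species_id")["trophic_category"]
    df = survey.copy()
    df["trophic_category"] = df["species_id"].map(cat)
    n_no_cat = int(df["trophic_category"].isna().sum())
    df = df.dropna(subset=["trophic_category"])
    df["sti"] = df["species_id"].map(sti)
    n_no_sti = int(df["sti"].isna().sum())
    df = df.dropna(subset=["sti"])
    df["threshold"] = df["site_id"].map(site_thresholds)
    df["thermal_class"] = np.where(df["sti"] >= df["threshold"], "resistant", "sensitive")
    out = (
        df.groupby(["site_id", "year", "thermal_class", "trophic_category"], as_index=False)
        .agg(abundance=("abundance", "sum"))
    )
    out["log_abundance"] = np.log1p(out["abundance"])
    sd = out["log_abundance"].std(ddof=1)
    out["z_log_abundance"] = (
        (out["log_abundance"] - out["log_abundance"].mean()) / sd if sd > 0 else 0.0
    )
    return out, ThermalTableReport(n_no_cat, n_no_sti)
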