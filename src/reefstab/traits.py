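"""Functional-trait space: imputation, Gower dissimilarity, PCoA, richness.

Species traits mix continuous (body size, trophic position, vulnerability,
thermal affinity), ordinal (gregariousness, water position) and nominal
(trophic category) variables with missing values.  Gaps are filled from
genus then family averages/modes; Gower dissimilarity handles the mixed
types; classical principal-coordinates analysis embeds species in a 3-axis
trait space; functional richness of a site is the fraction of the species
pool's convex-hull volume its species occupy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.spatial import ConvexHull, QhullError

from .simulate import GREGARIOUSNESS_LEVELS, WATER_POSITION_LEVELS

__all__ = [
    "CONTINUOUS_TRAITS",
    "ORDINAL_TRAITS",
    "NOMINAL_TRAITS",
    "TraitSpace",
    "resolve_traits",
    "gower_dissimilarity",
    "pcoa",
    "functional_richness",
    "site_functional_richness",
    "sample_coverage",
]

CONTINUOUS_TRAITS = ["body_size", "trophic_position", "vulnerability", "sti"]
ORDINAL_TRAITS = {
    "gregariousness": GREGARIOUSNESS_LEVELS,
    "water_position": WATER_POSITION_LEVELS,
}
NOMINAL_TRAITS = ["trophic_category"]


def resolve_traits(table: pd.DataFrame) -> pd.DataFrame:
    """Fill missing traits from genus means/modes, falling back to family.

    Continuous traits take the genus (else family) mean; ordinal traits take
    the genus (else family) modal category, ties resolved toward the lower
    category.  Rows with no gap are returned unchanged; traits missing at
    all three levels stay missing and the row is flagged in the
    ``unresolved`` column.
    """
    df = table.copy()
    trait_cols = [c for c in CONTINUOUS_TRAITS if c in df.columns]
    ord_cols = [c for c in ORDINAL_TRAITS if c in df.columns]

    def fill_from(level: str) -> None:
        if level not in df.columns:
            return
        for col in trait_cols:
            means = df.groupby(level)[col].transform("mean")
            df[col] = df[col].fillna(means)
        for col in ord_cols:
            levels = ORDINAL_TRAITS[col]

            def mode_lowest(s: pd.Series) -> object:
                s = s.dropna()
                if s.empty:
                    return np.nan
                counts = s.value_counts()
                best = counts[counts == counts.max()].index
                return min(best, key=levels.index)

            modes = df.groupby(level)[col].transform(mode_lowest)
            df[col] = df[col].fillna(modes)

    fill_from("genus")
    fill_from("family")
    df["unresolved"] = df[trait_cols + ord_cols].isna().any(axis=1)
    return df


def _encode(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Encode traits numerically for Gower: returns (values, is_nominal).

    Ordinal levels are scored by rank position rescaled to [0, 1] (so a
    3-level trait maps to 0, 1/2, 1), then treated like continuous traits
    with range normalisation; nominal traits contribute 0/1 mismatch.
    """
    cols = []
    nominal = []
    for c in CONTINUOUS_TRAITS:
        if c in table.columns:
            cols.append(pd.to_numeric(table[c]).to_numpy(dtype=float))
            nominal.append(False)
    for c, levels in ORDINAL_TRAITS.items():
        if c in table.columns:
            k = len(levels) - 1
            scored = table[c].map({lv: i / k for i, lv in enumerate(levels)} if k else {levels[0]: 0.0})
            cols.append(scored.to_numpy(dtype=float))
            nominal.append(False)
    for c in NOMINAL_TRAITS:
        if c in table.columns:
            codes = pd.Categorical(table[c]).codes.astype(float)
            codes[codes < 0] = np.nan
            cols.append(codes)
            nominal.append(True)
    if not cols:
        raise ValueError("no recognised trait columns")
    return np.column_stack(cols), np.asarray(nominal)


def gower_dissimilarity(table: pd.DataFrame) -> np.ndarray:
    """Pairwise Gower dissimilarity in [0, 1] over mixed-type traits.

    Per-trait distances (continuous/ordinal: |dx|/range over the pool;
    nominal: mismatch) are averaged over the traits observed in *both*
    species of a pair; a pair sharing no observed trait is an error.
    Invariant to affine rescaling of any continuous trait.
    """
    x, is_nominal = _encode(table)
    n, p = x.shape
    rng_ = np.nanmax(x, axis=0) - np.nanmin(x, axis=0)
    d = np.zeros((n, n))
    ids = table["species_id"].tolist() if "species_id" in table.columns else list(range(n))
    for a in range(n):
        for b in range(a + 1, n):
            num = den = 0.0
            for k in range(p):
                xa, xb = x[a, k], x[b, k]
                if np.isnan(xa) or np.isnan(xb):
                    continue
                if is_nominal[k]:
                    num += float(xa != xb)
                elif rng_[k] > 0:
                    num += abs(xa - xb) / rng_[k]
                # zero-range continuous trait: distance 0, still observed
                den += 1.0
            if den == 0:
                raise ValueError(f"species pair ({ids[a]}, {ids[b]}) share no observed trait")
            d[a, b] = d[b, a] = num / den
    return d


@dataclass
class TraitSpace:
    """Principal-coordinates embedding of the species pool."""

    species_ids: list[str]
    coordinates: np.ndarray  # n_species x n_axes
    eigenvalues: np.ndarray  # all eigenvalues, descending
    variance_explained: float  # by the retained axes, over positive eigenvalues


def pcoa(
    dissimilarity: np.ndarray, species_ids: list[str] | None = None, n_axes: int = 3
) -> TraitSpace:
    """Classical metric scaling of a dissimilarity matrix.

    Double-centers -D^2/2, eigendecomposes, and returns the first ``n_axes``
    positive-eigenvalue axes scaled by sqrt(eigenvalue).  Negative
    eigenvalues (possible for non-Euclidean Gower input) receive no
    correction and are excluded from the variance-explained denominator; if
    fewer than ``n_axes`` positive axes exist the available ones are
    returned with a warning.
    """
    d = np.asarray(dissimilarity, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValueError("dissimilarity must be symmetric with zero diagonal")
    n = d.shape[0]
    if species_ids is None:
        species_ids = [str(i) for i in range(n)]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = 1e-10 * max(1.0, abs(evals[0])) if n else 0.0
    pos = evals > tol
    n_pos = int(pos.sum())
    k = min(n_axes, n_pos)
    if k < n_axes:
        warnings.warn(
            f"only {n_pos} positive eigenvalue(s); returning {k} axis(es)", stacklevel=2
        )
    coords = evecs[:, :k] * np.sqrt(np.maximum(evals[:k], 0.0))
    total_pos = float(evals[pos].sum())
    var_exp = float(evals[:k].sum() / total_pos) if total_pos > 0 else 0.0
    return TraitSpace(list(species_ids), coords, evals, var_exp)


def functional_richness(site_species: set[str] | list[str], space: TraitSpace) -> float:
    """Fraction of the pool's convex-hull volume filled by a site's species.

    NaN (site hull undefined) when the site has fewer than dim+1 species or
    its species are affinely degenerate (coplanar in 3-D).
    """
    coords = space.coordinates
    dim = coords.shape[1]
    try:
        pool_vol = ConvexHull(coords).volume
    except QhullError as exc:
        raise ValueError("species-pool hull is degenerate") from exc
    idx = [i for i, s in enumerate(space.species_ids) if s in set(site_species)]
    if len(idx) < dim + 1:
        return float("nan")
    try:
        site_vol = ConvexHull(coords[idx]).volume
    except QhullError:
        return float("nan")
    return float(site_vol / pool_vol)


def site_functional_richness(
    survey: pd.DataFrame, space: TraitSpace
) -> pd.DataFrame:
    """Per-site functional richness from an aggregated survey table."""
    rows = []
    for site_id, grp in survey.groupby("site_id"):
        fric = functional_richness(set(grp["species_id"].astype(str)), space)
        rows.append({"site_id": site_id, "functional_richness": fric})
    return pd.DataFrame(rows)


def sample_coverage(abundances) -> float:
    """Abundance-based sample-coverage estimate (completeness) in [0, 1].

    C_hat = 1 - (f1/n) * (n-1) f1 / ((n-1) f1 + 2 f2), with f1/f2 the
    singleton/doubleton counts and n the total count.  With no singletons
    the sample is estimated complete (1); an all-singleton sample scores 0.
    """
    x = np.asarray(abundances)
    if np.any(x < 0) or np.any(x != np.floor(x)):
        raise ValueError("abundances must be non-negative integers")
    n = int(x.sum())
    if n == 0:
        raise ValueError("total abundance is zero")
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    if f1 == 0:
        return 1.0
    denom = (n - 1) * f1 + 2 * f2
    if denom == 0:
        return 1.0 - f1 / n
    return 1.0 - (f1 / n) * ((n - 1) * f1 / denom)
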