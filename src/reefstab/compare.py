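"""MPA-vs-open-area comparison machinery.

Within each ecoregion, site timeseries are matched on a common year window
(the one retaining the most sites with at least two MPA and two open-area
sites), sites are matched in space (within the maximum MPA-MPA distance, or
a fixed band), every stability/asynchrony measure is recomputed leaving one
species out at a time to obtain a jackknife variance, and MPA and open-area
values are combined into a Hedge's g effect size per metacommunity and
measure.  The effect sizes feed the hierarchical Bayesian meta-analysis in
:mod:`reefstab.meta`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import haversine_matrix
from .datamodel import CommunityMatrix, MetacommunityTensor, build_tensor
from .stability import metacommunity_measures

__all__ = [
    "YearMatch",
    "match_years",
    "SpatialMatch",
    "spatial_match",
    "jackknife",
    "hedges_g",
    "EffectSize",
    "metacommunity_effect_sizes",
]

MEASURES = ("GAS", "AAS", "ASS", "MPS", "SCA", "SSA", "ASA", "MPAS")
STABILITY_MEASURES = ("GAS", "AAS", "ASS", "MPS")


@dataclass
class YearMatch:
    years: np.ndarray
    site_ids: list[str]
    excluded_reason: str | None = None

    @property
    def feasible(self) -> bool:
        return self.excluded_reason is None


def match_years(
    site_years: dict[str, set[int]],
    protection: dict[str, str],
    min_len: int = 5,
    min_mpa: int = 2,
    min_oa: int = 2,
) -> YearMatch:
    """Choose the year window maximising the number of completely covered sites.

    Candidate windows are contiguous runs of the pooled observed years with
    length >= ``min_len``; a site qualifies when it was sampled in every
    window year.  Feasible windows need at least ``min_mpa`` MPA and
    ``min_oa`` open-area sites.  Ties go to the longer window, then the
    earlier start.
    """
    all_years = sorted({y for ys in site_years.values() for y in ys})
    best: tuple[int, int, int] | None = None  # (-n_sites, -length, start_index)
    best_sites: list[str] = []
    best_years: list[int] = []
    n = len(all_years)
    saw_window = False
    for i in range(n):
        for j in range(i + min_len - 1, n):
            window = all_years[i : j + 1]
            saw_window = True
            wset = set(window)
            covered = [s for s, ys in site_years.items() if wset <= ys]
            n_mpa = sum(protection[s] == "MPA" for s in covered)
            n_oa = sum(protection[s] == "OA" for s in covered)
            if n_mpa < min_mpa or n_oa < min_oa:
                continue
            key = (-len(covered), -len(window), i)
            if best is None or key < best:
                best = key
                best_sites = sorted(covered)
                best_years = window
    if best is None:
        # diagnose the binding constraint for the report
        n_mpa_ever = sum(v == "MPA" for v in protection.values())
        n_oa_ever = sum(v == "OA" for v in protection.values())
        if n_mpa_ever < min_mpa:
            reason = "min_mpa"
        elif n_oa_ever < min_oa:
            reason = "min_oa"
        elif not saw_window:
            reason = "min_len"
        else:
            reason = "no-common-window"
        return YearMatch(np.array([], dtype=int), [], reason)
    return YearMatch(np.asarray(best_years, dtype=int), best_sites)


@dataclass
class SpatialMatch:
    """Per-focal-MPA neighbourhoods within the matching radius."""

    scale_km: float
    mpa_sites: list[str]
    oa_neighborhoods: dict[str, list[str]]  # focal MPA -> OA sites in radius
    flags: set[str] = field(default_factory=set)


def spatial_match(
    sites: pd.DataFrame,
    scale: float | str = "max-mpa-distance",
    distances: pd.DataFrame | None = None,
) -> SpatialMatch:
    """Match open-area sites to each focal MPA within a spatial scale.

    ``scale`` is either a radius in km or "max-mpa-distance" (the maximum
    distance separating any two MPA sites).  Distances come from a supplied
    sea-distance matrix or great-circle from coordinates.  All MPA sites
    fall inside every focal radius at the max-MPA-distance scale by
    construction, so MPA-side measures are evaluated once; open-area
    neighbourhoods are kept per focal MPA.
    """
    ids = sites["site_id"].astype(str).tolist()
    if distances is not None:
        d = distances.loc[ids, ids].to_numpy(dtype=float)
    else:
        d = haversine_matrix(sites["latitude"].to_numpy(), sites["longitude"].to_numpy())
    prot = dict(zip(ids, sites["protection"]))
    mpa = [s for s in ids if prot[s] == "MPA"]
    oa = [s for s in ids if prot[s] == "OA"]
    if len(mpa) < 2:
        raise ValueError("spatial matching needs at least 2 MPA sites")
    pos = {s: k for k, s in enumerate(ids)}
    if scale == "max-mpa-distance":
        radius = float(max(d[pos[a], pos[b]] for a in mpa for b in mpa))
    else:
        radius = float(scale)
    flags: set[str] = set()
    hoods = {}
    for focal in mpa:
        near_oa = [s for s in oa if d[pos[focal], pos[s]] <= radius]
        hoods[focal] = near_oa
    if all(len(v) == 0 for v in hoods.values()):
        flags.add("no-oa-in-scale")
    return SpatialMatch(radius, mpa, hoods, flags)


def _jackknife_variance(pseudo: np.ndarray) -> tuple[float, set[str]]:
    """((S-1)/S) sum (theta_(j) - mean)^2 over the defined pseudo-values."""
    flags: set[str] = set()
    ok = np.isfinite(pseudo)
    if not ok.all():
        flags.add("pseudo-value-dropped")
    vals = pseudo[ok]
    k = len(vals)
    if k < 2:
        return float("nan"), flags | {"too-few-pseudo-values"}
    return (k - 1) / k * float(((vals - vals.mean()) ** 2).sum()), flags


def jackknife(
    tensor: MetacommunityTensor, measure: str, family: str = "gross"
) -> tuple[float, np.ndarray, float, set[str]]:
    """Leave-one-species-out resampling of a metacommunity measure.

    Returns (observed, pseudo-values, jackknife variance, flags).  Pseudo
    values undefined after a deletion (degenerate variance) are dropped and
    the effective S adjusted (flagged).  The variance is
    ((S-1)/S) * sum_j (theta_(j) - mean theta)^2.
    """
    obs, pseudos, variances, flags = jackknife_all(tensor, (measure,), family)
    return obs[measure], pseudos[measure], variances[measure], flags[measure]


def jackknife_all(
    tensor: MetacommunityTensor, measures: tuple[str, ...], family: str = "gross"
) -> tuple[dict[str, float], dict[str, np.ndarray], dict[str, float], dict[str, set[str]]]:
    """Jackknife several measures in a single leave-one-species-out sweep."""
    s = len(tensor.species_ids)
    if s < 2:
        raise ValueError("jackknife needs at least 2 species")
    observed = metacommunity_measures(tensor, family)
    deletions = [metacommunity_measures(tensor.drop_species(j), family) for j in range(s)]
    obs, pseudos, variances, flags = {}, {}, {}, {}
    for m in measures:
        pseudo = np.array([d[m] for d in deletions])
        var, fl = _jackknife_variance(pseudo)
        obs[m], pseudos[m], variances[m], flags[m] = observed[m], pseudo, var, fl
    return obs, pseudos, variances, flags


@dataclass
class EffectSize:
    metacommunity_id: str
    measure: str
    g: float
    variance: float
    n_mpa_species: int
    n_oa_species: int
    flags: set[str] = field(default_factory=set)


def hedges_g(
    theta_mpa: float,
    var_mpa: float,
    n_mpa: int,
    theta_oa: float,
    var_oa: float,
    n_oa: int,
) -> tuple[float, float, set[str]]:
    """Hedge's g for an MPA-minus-open-area difference with jackknife variances.

    The jackknife variances estimate Var(theta-hat); rescaling by the number
    of species entering the jackknife (var * n) recovers a per-observation
    variance for the pooled SD:

        s_p^2 = ((n1-1) var1 n1 + (n2-1) var2 n2) / (n1 + n2 - 2)
        g     = J (theta1 - theta2) / s_p,   J = 1 - 3/(4(n1+n2) - 9)

    Sampling variance by the standard large-sample formula
    (n1+n2)/(n1 n2) + g^2/(2(n1+n2)).  Positive g = higher value in MPAs.
    """
    if var_mpa < 0 or var_oa < 0:
        raise ValueError("variances must be non-negative")
    n = n_mpa + n_oa
    sp2 = ((n_mpa - 1) * var_mpa * n_mpa + (n_oa - 1) * var_oa * n_oa) / (n - 2)
    if sp2 <= 0:
        return float("nan"), float("nan"), {"zero-pooled-sd"}
    j = 1.0 - 3.0 / (4.0 * n - 9.0)
    g = j * (theta_mpa - theta_oa) / np.sqrt(sp2)
    var_g = n / (n_mpa * n_oa) + g**2 / (2.0 * n)
    return float(g), float(var_g), set()


def metacommunity_effect_sizes(
    matrices: dict[str, CommunityMatrix],
    sites: pd.DataFrame,
    family: str = "gross",
    measures: tuple[str, ...] = MEASURES,
    scale: float | str = "max-mpa-distance",
    distances: pd.DataFrame | None = None,
    min_len: int = 5,
    min_mpa: int = 2,
    min_oa: int = 2,
) -> tuple[list[EffectSize], dict[str, str]]:
    """Per-ecoregion Hedge's g effect sizes for the requested measures.

    For each ecoregion: match years, match space, build the MPA tensor (all
    MPA sites, one evaluation) and one open-area tensor per focal-MPA
    neighbourhood (results averaged across focal MPAs, mirroring how the
    same open sites may serve several focal MPAs), jackknife both sides,
    and combine into Hedge's g.  Returns the effect sizes plus a dict of
    excluded ecoregions with reasons.
    """
    effects: list[EffectSize] = []
    excluded: dict[str, str] = {}
    for eco, eco_sites in sites.groupby("ecoregion"):
        ids = [s for s in eco_sites["site_id"].astype(str) if s in matrices]
        eco_sites = eco_sites[eco_sites["site_id"].astype(str).isin(ids)]
        prot = dict(zip(eco_sites["site_id"].astype(str), eco_sites["protection"]))
        site_years = {s: set(int(y) for y in matrices[s].years) for s in ids}
        ym = match_years(site_years, prot, min_len, min_mpa, min_oa)
        if not ym.feasible:
            excluded[str(eco)] = ym.excluded_reason
            continue
        kept = eco_sites[eco_sites["site_id"].astype(str).isin(ym.site_ids)]
        try:
            sm = spatial_match(kept, scale=scale, distances=distances)
        except ValueError as exc:
            excluded[str(eco)] = str(exc)
            continue
        if "no-oa-in-scale" in sm.flags:
            excluded[str(eco)] = "no-oa-in-scale"
            continue
        mpa_tensor = build_tensor(
            {s: matrices[s] for s in sm.mpa_sites}, ym.years, ecoregion=str(eco)
        )
        mpa_obs, _, mpa_var, mpa_fl = jackknife_all(mpa_tensor, measures, family)
        # open-area side: one tensor per focal neighbourhood, averaged over
        # focal MPAs; identical neighbourhoods are computed once and weighted
        # by how many focal MPAs share them
        hood_counts: dict[tuple[str, ...], int] = {}
        for oa_ids in sm.oa_neighborhoods.values():
            if oa_ids:
                key = tuple(sorted(oa_ids))
                hood_counts[key] = hood_counts.get(key, 0) + 1
        oa_runs = []  # (weight, obs, var, n_species)
        for key, wt in hood_counts.items():
            oa_tensor = build_tensor(
                {s: matrices[s] for s in key}, ym.years, ecoregion=str(eco)
            )
            if len(oa_tensor.species_ids) < 2:
                continue
            obs, _, var, _ = jackknife_all(oa_tensor, measures, family)
            oa_runs.append((wt, obs, var, len(oa_tensor.species_ids)))
        for measure in measures:
            th_mpa, v_mpa = mpa_obs[measure], mpa_var[measure]
            picks = [
                (wt, obs[measure], var[measure], n)
                for wt, obs, var, n in oa_runs
                if np.isfinite(obs[measure]) and np.isfinite(var[measure])
            ]
            flags = set(mpa_fl[measure])
            if not picks or not np.isfinite(th_mpa) or not np.isfinite(v_mpa):
                effects.append(
                    EffectSize(str(eco), measure, float("nan"), float("nan"),
                               len(mpa_tensor.species_ids), 0, flags | {"undefined"})
                )
                continue
            wts = np.array([p[0] for p in picks], dtype=float)
            wts /= wts.sum()
            th_oa = float((wts * np.array([p[1] for p in picks])).sum())
            v_oa = float((wts * np.array([p[2] for p in picks])).sum())
            n_oa_sp = int(round((wts * np.array([p[3] for p in picks])).sum()))
            g, var_g, fl = hedges_g(
                th_mpa, v_mpa, len(mpa_tensor.species_ids), th_oa, v_oa, n_oa_sp
            )
            effects.append(
                EffectSize(str(eco), measure, g, var_g,
                           len(mpa_tensor.species_ids), n_oa_sp, flags | fl)
            )
    return effects, excluded
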