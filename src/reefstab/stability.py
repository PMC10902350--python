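"""Hierarchical stability and asynchrony partitioning of community timeseries.

Stability is the inverse coefficient of variation (temporal mean / SD) of an
abundance series; asynchrony measures how far components (species within a
site, sites within a metacommunity, populations of one species across sites)
fluctuate out of phase.  Two asynchrony families are provided:

* **Gross** — minus the abundance-weighted mean Pearson correlation between
  each component and the summed series of all other components; ranges over
  [-1, 1] (1 = perfect compensation, -1 = perfect synchrony).
* **Loreau–de Mazancourt (LdM)** — one minus the variance ratio
  ``phi = var(total) / (sum of component SDs)**2``; ranges over [0, 1].

At the metacommunity level both families are applied at four hierarchical
levels: among sites (spatial community), among populations of each species
across sites (spatial species), among species within sites averaged across
sites (average species), and among metapopulation totals (metapopulation).

Undefined values (zero-variance series) propagate as NaN with named flags,
never as silent zeros.  All measures are invariant to multiplying every
abundance by a positive constant — the coefficient-of-variation property
that motivates using a sampling-effort offset downstream instead of
densities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import CommunityMatrix, MetacommunityTensor

__all__ = [
    "StabilitySummary",
    "MetacommunityMeasures",
    "NullResult",
    "alpha_stability",
    "species_stability",
    "gross_asynchrony",
    "ldm_synchrony",
    "ldm_asynchrony",
    "detrend",
    "community_summary",
    "metacommunity_stability",
    "metacommunity_asynchrony",
    "metacommunity_measures",
    "cyclic_shift",
    "cyclic_shift_null",
]

DDOF = 1  # sample SD throughout; configurable per-call where it matters

# SDs below this relative level are round-off from constant series and are
# treated as zero variance
_REL_TOL = 1e-12


def _sd(x: np.ndarray, ddof: int = DDOF) -> float:
    return float(np.std(x, ddof=ddof))


def _degenerate(sd: float, scale: float) -> bool:
    return sd <= _REL_TOL * max(1.0, abs(scale))


def alpha_stability(matrix: CommunityMatrix, ddof: int = DDOF) -> float:
    """Inverse CV (mean/SD) of total community abundance; NaN if SD is zero."""
    tot = matrix.totals()
    sd = _sd(tot, ddof)
    mu = float(np.mean(tot))
    if _degenerate(sd, mu):
        return float("nan")
    return mu / sd


def species_stability(matrix: CommunityMatrix, ddof: int = DDOF) -> float:
    """Inverse of the abundance-weighted mean species CV.

    Algebraically ``mu_total / sum_j sigma_j``: the weights mu_j/mu_total
    multiply CVs sigma_j/mu_j, so the species means cancel.
    """
    mu_tot = float(matrix.totals().mean())
    sd_sum = float(sum(_sd(matrix.abundance[:, j], ddof) for j in range(matrix.n_species)))
    if _degenerate(sd_sum, mu_tot) or mu_tot == 0:
        return float("nan")
    return mu_tot / sd_sum


def _weighted_gross(series: np.ndarray, weights: np.ndarray) -> tuple[float, set[str]]:
    """Gross asynchrony of component rows ``series`` (C x T) with weights.

    Each component is correlated with the sum of the others; terms whose
    component or complement series has zero variance are dropped and the
    remaining weights renormalised to 1 (flagged).
    """
    flags: set[str] = set()
    c = series.shape[0]
    if c < 2:
        return float("nan"), {"single-component"}
    total = series.sum(axis=0)
    vals, wts = [], []
    for j in range(c):
        rest = total - series[j]
        if _degenerate(np.std(series[j]), np.mean(series[j])) or _degenerate(
            np.std(rest), np.mean(rest)
        ):
            flags.add("zero-variance-component")
            continue
        r = float(np.corrcoef(series[j], rest)[0, 1])
        vals.append(r)
        wts.append(weights[j])
    if not vals:
        return float("nan"), flags | {"all-degenerate"}
    w = np.asarray(wts)
    w = w / w.sum()
    return float(-(w * np.asarray(vals)).sum()), flags


def gross_asynchrony(matrix: CommunityMatrix) -> float:
    """Weighted Gross asynchrony among species in one site, in [-1, 1]."""
    val, _ = gross_asynchrony_flagged(matrix)
    return val


def gross_asynchrony_flagged(matrix: CommunityMatrix) -> tuple[float, set[str]]:
    mu = matrix.abundance.mean(axis=0)
    mu_tot = mu.sum()
    if mu_tot == 0:
        return float("nan"), {"empty-community"}
    return _weighted_gross(matrix.abundance.T, mu / mu_tot)


def ldm_synchrony(matrix: CommunityMatrix, ddof: int = DDOF) -> float:
    """LdM variance-ratio synchrony phi = var(total)/(sum_j sd_j)^2 in [0, 1]."""
    sd_sum = sum(_sd(matrix.abundance[:, j], ddof) for j in range(matrix.n_species))
    if _degenerate(sd_sum, float(matrix.totals().mean())):
        return float("nan")
    var_tot = float(np.var(matrix.totals(), ddof=ddof))
    return var_tot / sd_sum**2


def ldm_asynchrony(matrix: CommunityMatrix, ddof: int = DDOF) -> float:
    """1 - phi, in [0, 1]."""
    phi = ldm_synchrony(matrix, ddof)
    return float("nan") if np.isnan(phi) else 1.0 - phi


def detrend(matrix: CommunityMatrix) -> CommunityMatrix:
    """Remove each species' OLS linear trend on year, preserving its mean.

    The residual series keeps mu_j and replaces sigma_j with the residual SD,
    so stability measures on the detrended matrix isolate fluctuation around
    trend.  Idempotent.  Residuals below round-off are clipped to the mean so
    abundances stay non-negative for perfectly linear series.
    """
    x = matrix.years.astype(float)
    out = np.empty_like(matrix.abundance)
    for j in range(matrix.n_species):
        y = matrix.abundance[:, j]
        slope, intercept = np.polyfit(x, y, 1) if len(x) > 1 else (0.0, float(y.mean()))
        resid = y - (slope * x + intercept)
        out[:, j] = np.clip(resid + y.mean(), 0.0, None)
    return CommunityMatrix(matrix.site_id, matrix.years, list(matrix.species_ids), out)


@dataclass
class StabilitySummary:
    """Site-level stability/asynchrony bundle."""

    site_id: str
    alpha_stability: float
    species_stability: float
    gross_asynchrony: float
    ldm_asynchrony: float
    degenerate_flags: set[str] = field(default_factory=set)


def community_summary(matrix: CommunityMatrix, ddof: int = DDOF) -> StabilitySummary:
    g, flags = gross_asynchrony_flagged(matrix)
    a = alpha_stability(matrix, ddof)
    s = species_stability(matrix, ddof)
    l = ldm_asynchrony(matrix, ddof)
    if np.isnan(a):
        flags.add("zero-variance")
    return StabilitySummary(matrix.site_id, a, s, g, l, flags)


# ---------------------------------------------------------------------------
# metacommunity level
# ---------------------------------------------------------------------------


def _site_totals(t: MetacommunityTensor) -> np.ndarray:
    """N x T total community abundance per site."""
    return t.abundance.sum(axis=1)


def _metapop(t: MetacommunityTensor) -> np.ndarray:
    """S x T total abundance of each species summed over sites."""
    return t.abundance.sum(axis=0)


def metacommunity_stability(tensor: MetacommunityTensor, ddof: int = DDOF) -> dict[str, float]:
    """Four stability measures of the metacommunity hierarchy.

    GAS  gamma stability            mu_M / sd(metacommunity total)
    AAS  average alpha stability    mu_M / sum_i sd(site total_i)
    ASS  average species stability  mu_M / sum_i sum_j sd(A_j(i))
    MPS  metapopulation stability   mu_M / sum_j sd(metapopulation_j)

    Each is the inverse of an abundance-weighted mean CV; the weighting
    collapses to the SD sums shown.  NaN where the SD sum (or sd_M) is zero.
    """
    site_tot = _site_totals(tensor)
    meta_tot = site_tot.sum(axis=0)
    mu_m = float(meta_tot.mean())
    sd_m = _sd(meta_tot, ddof)
    sd_sites = sum(_sd(site_tot[i], ddof) for i in range(tensor.n_sites))
    sd_pops = float(
        sum(
            _sd(tensor.abundance[i, j], ddof)
            for i in range(tensor.n_sites)
            for j in range(len(tensor.species_ids))
        )
    )
    metapop = _metapop(tensor)
    sd_meta_pops = sum(_sd(metapop[j], ddof) for j in range(metapop.shape[0]))

    def ratio(num: float, den: float) -> float:
        return num / den if not _degenerate(den, num) else float("nan")

    return {
        "GAS": ratio(mu_m, sd_m),
        "AAS": ratio(mu_m, sd_sites),
        "ASS": ratio(mu_m, sd_pops),
        "MPS": ratio(mu_m, sd_meta_pops),
    }


def _ldm_ratio(components: np.ndarray, ddof: int = DDOF) -> float:
    """phi of component rows (C x T): var(sum)/(sum sd)^2."""
    sd_sum = sum(_sd(components[j], ddof) for j in range(components.shape[0]))
    if _degenerate(sd_sum, float(components.sum(axis=0).mean())):
        return float("nan")
    return float(np.var(components.sum(axis=0), ddof=ddof)) / sd_sum**2


def metacommunity_asynchrony(
    tensor: MetacommunityTensor, family: str = "gross", ddof: int = DDOF
) -> dict[str, float]:
    """Four asynchrony measures of the metacommunity hierarchy.

    SCA   spatial community asynchrony — among site totals
    SSA   spatial species asynchrony — among populations of each species
          across sites, abundance-weighted over species and sites
    ASA   average species asynchrony — site-level species asynchrony
          abundance-weighted across sites
    MPAS  metapopulation asynchrony — among metapopulation totals

    family="gross" uses weighted Gross correlations (range [-1, 1]);
    family="ldm" applies the variance ratio at each level and reports
    1 - phi (range [0, 1]).
    """
    if family not in ("gross", "ldm"):
        raise ValueError("family must be 'gross' or 'ldm'")
    site_tot = _site_totals(tensor)  # N x T
    metapop = _metapop(tensor)  # S x T
    n, s, _ = tensor.abundance.shape
    mu_sites = site_tot.mean(axis=1)  # per-site mean total
    mu_meta = mu_sites.sum()
    w_sites = mu_sites / mu_meta if mu_meta > 0 else np.full(n, np.nan)
    mu_species = metapop.mean(axis=1)
    w_species = mu_species / mu_meta if mu_meta > 0 else np.full(s, np.nan)

    if family == "gross":
        sca, _ = _weighted_gross(site_tot, w_sites)
        mpas, _ = _weighted_gross(metapop, w_species)
        # SSA: for each population A_j(i), correlate with the same species
        # summed over the other sites; weights mu_j(i)/mu collapse from
        # (mu_j(i)/mu_i)(mu_i/mu); degenerate terms dropped + renormalised.
        vals, wts = [], []
        for i in range(n):
            for j in range(s):
                pop = tensor.abundance[i, j]
                rest = metapop[j] - pop
                if _degenerate(np.std(pop), np.mean(pop)) or _degenerate(
                    np.std(rest), np.mean(rest)
                ):
                    continue
                vals.append(float(np.corrcoef(pop, rest)[0, 1]))
                wts.append(tensor.abundance[i, j].mean() / mu_meta)
        if vals:
            w = np.asarray(wts)
            ssa = float(-(w / w.sum() * np.asarray(vals)).sum())
        else:
            ssa = float("nan")
        # ASA: abundance-weighted mean of site-level Gross asynchronies
        etas = np.array(
            [
                _weighted_gross(tensor.abundance[i], _safe_weights(tensor.abundance[i]))[0]
                for i in range(n)
            ]
        )
        ok = ~np.isnan(etas)
        asa = float((w_sites[ok] / w_sites[ok].sum() * etas[ok]).sum()) if ok.any() else float("nan")
        return {"SCA": sca, "SSA": ssa, "ASA": asa, "MPAS": mpas}

    # LdM family: 1 - phi at each level
    phi_spatial = _ldm_ratio(site_tot, ddof)
    phi_metapop = _ldm_ratio(metapop, ddof)
    # spatial-species: per species, phi across its site populations,
    # abundance-weighted over species
    phis, wts = [], []
    for j in range(s):
        p = _ldm_ratio(tensor.abundance[:, j, :], ddof)
        if not np.isnan(p):
            phis.append(p)
            wts.append(w_species[j])
    ssa = float(1 - (np.asarray(wts) / np.sum(wts) * np.asarray(phis)).sum()) if phis else float("nan")
    # average-species: site-level phi, abundance-weighted across sites
    phis_site = np.array([_ldm_ratio(tensor.abundance[i], ddof) for i in range(n)])
    ok = ~np.isnan(phis_site)
    asa = (
        float(1 - (w_sites[ok] / w_sites[ok].sum() * phis_site[ok]).sum())
        if ok.any()
        else float("nan")
    )
    return {
        "SCA": 1 - phi_spatial if not np.isnan(phi_spatial) else float("nan"),
        "SSA": ssa,
        "ASA": asa,
        "MPAS": 1 - phi_metapop if not np.isnan(phi_metapop) else float("nan"),
    }


def _safe_weights(series: np.ndarray) -> np.ndarray:
    mu = series.mean(axis=1)
    tot = mu.sum()
    return mu / tot if tot > 0 else np.full(series.shape[0], np.nan)


@dataclass
class MetacommunityMeasures:
    ecoregion: str
    family: str
    values: dict[str, float]

    def __getitem__(self, key: str) -> float:
        return self.values[key]


def metacommunity_measures(
    tensor: MetacommunityTensor, family: str = "gross", ddof: int = DDOF
) -> MetacommunityMeasures:
    vals = metacommunity_stability(tensor, ddof)
    vals.update(metacommunity_asynchrony(tensor, family, ddof))
    return MetacommunityMeasures(tensor.ecoregion, family, vals)


# ---------------------------------------------------------------------------
# cyclic-shift null model
# ---------------------------------------------------------------------------


def cyclic_shift(matrix: CommunityMatrix, rng: np.random.Generator) -> CommunityMatrix:
    """Independently rotate each species' series by a uniform offset (0..T-1).

    Preserves each series' values and circular order (hence autocorrelation)
    while destroying cross-species phase relationships.
    """
    t = matrix.n_years
    shifted = np.empty_like(matrix.abundance)
    for j in range(matrix.n_species):
        k = int(rng.integers(0, t))
        shifted[:, j] = np.roll(matrix.abundance[:, j], k)
    return CommunityMatrix(matrix.site_id, matrix.years, list(matrix.species_ids), shifted)


@dataclass
class NullResult:
    observed: float
    null_values: np.ndarray
    p_value: float
    ses: float
    flags: set[str] = field(default_factory=set)


def cyclic_shift_null(
    matrix: CommunityMatrix,
    statistic,
    n_iter: int = 999,
    seed: int | np.random.Generator = 0,
) -> NullResult:
    """Cyclic-shift permutation test of ``statistic(matrix)``.

    The observed matrix counts as one realization of the null model: with
    ``n_iter`` shifted realizations the two-sided p-value is the fraction of
    the n_iter + 1 values at least as far from the null mean as the observed
    one, so the minimum attainable p is 1/(n_iter + 1).  SES is
    (observed - null mean)/null SD, NaN (flagged) when the null SD is zero.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = float(statistic(matrix))
    null_values = np.array(
        [float(statistic(cyclic_shift(matrix, rng))) for _ in range(n_iter)]
    )
    combined = np.append(null_values, observed)
    center = combined.mean()
    p = float(np.mean(np.abs(combined - center) >= np.abs(observed - center) - 1e-12))
    null_sd = null_values.std(ddof=1) if n_iter > 1 else 0.0
    flags: set[str] = set()
    if not np.isfinite(null_sd):
        null_sd = 0.0
        flags.add("nan-statistic")
    if null_sd == 0:
        ses = float("nan")
        flags.add("degenerate-null")
        p = 1.0
    else:
        ses = (observed - null_values.mean()) / null_sd
    return NullResult(observed, null_values, p, float(ses), flags)
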