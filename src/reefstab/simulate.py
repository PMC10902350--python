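"""Synthetic reef-fish survey, SST, trait and effect-size generators.

Everything downstream of raw data can be exercised on these generators with
known ground truth: species fluctuate as exponentiated correlated Gaussian
series (equicorrelated at a controllable target, so Gross/LdM synchrony maps
to the correlation analytically), abundances are lognormal-scale counts,
SST is a seasonal cycle with injectable warm anomalies, and traits mix
continuous and ordinal variables with missing values.

One seed governs a scenario; per-site sub-streams are derived
deterministically, so adding a site leaves existing series untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mhw import SSTSeries

__all__ = [
    "SimConfig",
    "ScenarioConfig",
    "simulate_metacommunity",
    "simulate_scenario",
    "simulate_sst",
    "simulate_traits",
    "simulate_effect_sizes",
]

GREGARIOUSNESS_LEVELS = ["solitary", "pairing", "schooling"]
WATER_POSITION_LEVELS = ["benthic", "demersal", "pelagic-reef", "pelagic"]
TROPHIC_CATEGORIES = ["carnivores", "grazers", "microphages", "planktivores"]


@dataclass
class SimConfig:
    """Ground-truth settings of one simulated metacommunity.

    target_correlation is the common pairwise correlation of the latent
    log-abundance series (feasible range (-1/(S-1), 1]); mpa_effect
    multiplies MPA abundances; mpa_correlation optionally overrides the
    correlation at MPA sites (lower correlation = more asynchronous, hence
    more stable, protected communities).  species_mean_sd spreads species'
    characteristic log-mean abundances (shared across sites), reproducing
    the steep abundance distributions of real fish communities in which a
    few species dominate.  regional_sd adds a metacommunity-wide year
    effect (a shared environmental driver, e.g. thermal stress) to every
    site's log-abundance; mpa_buffering scales how strongly MPA sites feel
    it (1 = as exposed as open sites, 0 = fully buffered).
    """

    n_sites: int = 6
    n_species: int = 15
    n_years: int = 20
    mean_log_abundance: float = 2.0
    sd_log_abundance: float = 0.5
    species_mean_sd: float = 1.0
    loading_sd: float = 0.0
    target_correlation: float = 0.3
    regional_sd: float = 0.0
    regional_sens_sd: float = 0.5
    mpa_effect: float = 1.0
    mpa_correlation: float | None = None
    mpa_buffering: float = 1.0
    frac_mpa: float = 0.5
    sampled_area: float = 250.0
    study_id: str = "sim"
    ecoregion: str = "sim-ecoregion"
    start_year: int = 2000
    counts: str = "round"  # or "poisson": lognormal-Poisson mixture
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years < 5:
            raise ValueError("n_years must be at least 5")
        for rho in (self.target_correlation, self.mpa_correlation):
            if rho is None:
                continue
            if not (-1.0 / (self.n_species - 1) < rho <= 1.0):
                raise ValueError(
                    f"correlation {rho} infeasible: equicorrelation of {self.n_species} "
                    f"series is positive semi-definite only for rho > {-1.0/(self.n_species-1):.4f}"
                )


def _equicorrelated_normals(
    rng: np.random.Generator,
    n_series: int,
    n_steps: int,
    rho: float,
    loading_sd: float = 0.0,
) -> np.ndarray:
    """S x T standard normals with common pairwise correlation rho.

    With ``loading_sd`` > 0 species load heterogeneously on the shared
    factor: x_j = lambda_j z + sqrt(1 - lambda_j^2) e_j with lambda_j drawn
    around sqrt(rho) (clipped to [0, 1]), so the mean pairwise correlation
    stays near rho while species differ in how strongly they track the
    community-wide driver.  loading_sd = 0 gives exact equicorrelation.
    """
    if rho >= 0:
        z = rng.standard_normal(n_steps)
        e = rng.standard_normal((n_series, n_steps))
        lam = np.sqrt(rho)
        if loading_sd > 0:
            lam = np.clip(lam + loading_sd * rng.standard_normal(n_series), 0.0, 1.0)[:, None]
        return lam * z + np.sqrt(1.0 - lam**2) * e
    if loading_sd > 0:
        raise ValueError("heterogeneous loadings require rho >= 0")
    corr = np.full((n_series, n_series), rho)
    np.fill_diagonal(corr, 1.0)
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(n_series))
    return chol @ rng.standard_normal((n_series, n_steps))


def simulate_metacommunity(
    config: SimConfig, sites: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a survey table and site metadata for one metacommunity.

    Returns (survey, sites) DataFrames in the package's long formats.  With
    ``counts="round"`` abundances are exponentiated latent series rounded to
    integers; ``counts="poisson"`` draws Poisson counts around the latent
    intensity instead (extra observation noise).
    """
    cfg = config
    if sites is None:
        n_mpa = int(round(cfg.frac_mpa * cfg.n_sites))
        # intersperse MPA and open sites along the transect (as in real MPA
        # networks); clustering all MPAs at one end would confound protection
        # with position and with neighbourhood size in spatial matching
        mpa_idx = set(np.round(np.linspace(0, cfg.n_sites - 1, n_mpa)).astype(int)) if n_mpa else set()
        protections = ["MPA" if i in mpa_idx else "OA" for i in range(cfg.n_sites)]
        sites = pd.DataFrame(
            {
                "site_id": [f"{cfg.ecoregion}-s{i:02d}" for i in range(cfg.n_sites)],
                "ecoregion": cfg.ecoregion,
                "protection": protections,
                "latitude": -20.0 + 0.05 * np.arange(cfg.n_sites),
                "longitude": 150.0 + 0.05 * np.arange(cfg.n_sites),
                "study_id": cfg.study_id,
                "remoteness": 4.0 + np.arange(cfg.n_sites) % 5,
            }
        )
    years = np.arange(cfg.start_year, cfg.start_year + cfg.n_years)
    species = [f"sp{j:03d}" for j in range(cfg.n_species)]
    # species' characteristic abundances are a property of the species, so
    # one draw is shared by every site of the metacommunity
    sp_rng = np.random.default_rng([cfg.seed, 1237])
    species_mean = cfg.species_mean_sd * sp_rng.standard_normal(cfg.n_species)
    reg_rng = np.random.default_rng([cfg.seed, 4241])
    regional = cfg.regional_sd * reg_rng.standard_normal(cfg.n_years)
    reg_sens = 1.0 + cfg.regional_sens_sd * reg_rng.standard_normal(cfg.n_species)
    rows = []
    for i, site in sites.reset_index(drop=True).iterrows():
        rng = np.random.default_rng([cfg.seed, 7919, i])
        is_mpa = site["protection"] == "MPA"
        rho = cfg.mpa_correlation if (is_mpa and cfg.mpa_correlation is not None) else cfg.target_correlation
        latent = _equicorrelated_normals(
            rng, cfg.n_species, cfg.n_years, rho, loading_sd=cfg.loading_sd
        )
        sens = cfg.mpa_buffering if is_mpa else 1.0
        intensity = np.exp(
            cfg.mean_log_abundance
            + species_mean[:, None]
            + cfg.sd_log_abundance * latent
            + sens * reg_sens[:, None] * regional[None, :]
        )
        if is_mpa:
            intensity = intensity * cfg.mpa_effect
        if cfg.counts == "poisson":
            counts = rng.poisson(intensity).astype(float)
        else:
            counts = np.round(intensity)
        for j, sp in enumerate(species):
            for t, year in enumerate(years):
                rows.append(
                    (site["site_id"], int(year), sp, counts[j, t], cfg.sampled_area, site["study_id"])
                )
    survey = pd.DataFrame(
        rows, columns=["site_id", "year", "species_id", "abundance", "sampled_area", "study_id"]
    )
    return survey, sites


@dataclass
class ScenarioConfig:
    """A multi-ecoregion study scenario for end-to-end runs.

    The default effect settings encode a protection benefit the way MPAs are
    expected to act: larger population sizes (mpa_effect > 1) and more
    asynchronous species fluctuations (mpa_correlation below the open-area
    correlation).  Counts are lognormal-Poisson, so larger populations also
    fluctuate relatively less (demographic/observation noise shrinks with
    abundance) — together these raise every stability measure at MPA sites.
    """

    n_ecoregions: int = 2
    n_sites: int = 12
    n_species: int = 15
    n_years: int = 28
    mean_log_abundance: float = 1.5
    sd_log_abundance: float = 0.4
    species_mean_sd: float = 0.5
    loading_sd: float = 0.0
    regional_sd: float = 0.4
    oa_correlation: float = 0.4
    mpa_correlation: float = 0.05
    mpa_effect: float = 3.0
    mpa_buffering: float = 0.25
    seed: int = 0
    effect: bool = True  # False = null scenario: MPA and OA identical

    def site_config(self, e: int) -> SimConfig:
        return SimConfig(
            n_sites=self.n_sites,
            n_species=self.n_species,
            n_years=self.n_years,
            mean_log_abundance=self.mean_log_abundance,
            sd_log_abundance=self.sd_log_abundance,
            species_mean_sd=self.species_mean_sd,
            loading_sd=self.loading_sd,
            regional_sd=self.regional_sd,
            target_correlation=self.oa_correlation,
            mpa_correlation=self.mpa_correlation if self.effect else None,
            mpa_effect=self.mpa_effect if self.effect else 1.0,
            mpa_buffering=self.mpa_buffering if self.effect else 1.0,
            counts="poisson",
            ecoregion=f"eco{e:02d}",
            study_id=f"study{e:02d}",
            seed=self.seed + 104729 * (e + 1),
        )


def simulate_scenario(config: ScenarioConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate surveys and site metadata across several ecoregions."""
    surveys, sites = [], []
    for e in range(config.n_ecoregions):
        sv, st = simulate_metacommunity(config.site_config(e))
        st = st.copy()
        st["latitude"] = st["latitude"] + 2.0 * e
        surveys.append(sv)
        sites.append(st)
    return pd.concat(surveys, ignore_index=True), pd.concat(sites, ignore_index=True)


def simulate_sst(
    n_years: int,
    base: float = 22.0,
    seasonal_amplitude: float = 4.0,
    anomalies: list[tuple[str, int, float]] | None = None,
    noise_sd: float = 0.0,
    start_year: int = 1982,
    peak_doy: float = 31.0,
    seed: int = 0,
) -> SSTSeries:
    """Daily SST = base + seasonal sinusoid + boxcar anomalies + noise.

    ``anomalies`` is a list of (start_date, duration_days, magnitude_degC)
    boxcar warm events; overlapping windows are rejected.  The seasonal peak
    defaults to end of January (a Southern-Hemisphere reef).
    """
    dates = pd.date_range(f"{start_year}-01-01", f"{start_year + n_years - 1}-12-31", freq="D")
    t = np.arange(len(dates))
    seasonal = seasonal_amplitude * np.cos(2 * np.pi * (t - (peak_doy - 1)) / 365.25)
    sst = base + seasonal
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sst = sst + rng.normal(0.0, noise_sd, len(dates))
    occupied = np.zeros(len(dates), dtype=bool)
    for start, duration, magnitude in anomalies or []:
        if duration < 1:
            raise ValueError("anomaly duration must be >= 1 day")
        i0 = dates.get_loc(pd.Timestamp(start))
        i1 = i0 + duration
        if i1 > len(dates):
            raise ValueError(f"anomaly starting {start} extends beyond the series")
        if occupied[i0:i1].any():
            raise ValueError(f"anomaly starting {start} overlaps another anomaly")
        occupied[i0:i1] = True
        sst[i0:i1] += magnitude
    return SSTSeries(dates, sst)


def simulate_traits(n_species: int, missing_rate: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Mixed continuous/ordinal/nominal fish trait table with missing values.

    Continuous traits: body size (lognormal, cm), trophic position
    (uniform 2-4.6), intrinsic vulnerability (uniform 10-90) and STI
    (normal around 24 degC).  Ordinal: gregariousness and water position
    from their category sets.  Nominal: trophic category.  Species nest in
    genera and families so genus/family-level trait imputation is exercised.
    """
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    species = [f"sp{j:03d}" for j in range(n_species)]
    genus = [f"g{j // 3:03d}" for j in range(n_species)]
    family = [f"f{j // 9:03d}" for j in range(n_species)]
    df = pd.DataFrame(
        {
            "species_id": species,
            "genus": genus,
            "family": family,
            "body_size": np.round(np.exp(rng.normal(np.log(30.0), 0.6, n_species)), 1),
            "trophic_position": np.round(rng.uniform(2.0, 4.6, n_species), 2),
            "vulnerability": np.round(rng.uniform(10.0, 90.0, n_species), 1),
            "sti": np.round(rng.normal(24.0, 3.0, n_species), 2),
            "gregariousness": rng.choice(GREGARIOUSNESS_LEVELS, n_species),
            "water_position": rng.choice(WATER_POSITION_LEVELS, n_species),
            "trophic_category": rng.choice(TROPHIC_CATEGORIES, n_species),
        }
    )
    if missing_rate > 0:
        trait_cols = [
            "body_size",
            "trophic_position",
            "vulnerability",
            "sti",
            "gregariousness",
            "water_position",
        ]
        mask = rng.random((n_species, len(trait_cols))) < missing_rate
        for k, col in enumerate(trait_cols):
            df.loc[mask[:, k], col] = np.nan
    return df


def simulate_effect_sizes(
    m: int, mu: float, tau: float, sigma_m: np.ndarray, seed: int = 0
) -> pd.DataFrame:
    """Draw study effect sizes from the two-level normal meta-analytic model.

    theta_m ~ Normal(mu, tau^2); y_m ~ Normal(theta_m, sigma_m^2).  The
    ground-truth theta_m are recorded for recovery tests.
    """
    if tau < 0:
        raise ValueError("tau must be non-negative")
    sigma_m = np.asarray(sigma_m, dtype=float)
    if len(sigma_m) != m:
        raise ValueError("sigma_m must have length m")
    rng = np.random.default_rng(seed)
    theta = mu + tau * rng.standard_normal(m)
    y = theta + sigma_m * rng.standard_normal(m)
    return pd.DataFrame(
        {
            "metacommunity_id": [f"m{k:02d}" for k in range(m)],
            "g": y,
            "variance": sigma_m**2,
            "theta_true": theta,
        }
    )
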