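"""Core domain containers and data-curation steps for reef-fish survey timeseries.

The raw observational unit is a long-format survey table: one row per
(site, year, species [, replicate]) with a summed abundance count and the
area sampled.  Curation follows the standard protocol for multi-program
reef-fish monitoring data: replicate transects are summed within site-year,
and only sites with at least five years of observation are retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SURVEY_COLUMNS",
    "SITE_COLUMNS",
    "CommunityMatrix",
    "MetacommunityTensor",
    "SchemaError",
    "ValidationError",
    "read_survey_table",
    "read_site_table",
    "write_survey_table",
    "aggregate_site_year",
    "build_community_matrices",
    "filter_min_years",
    "build_tensor",
    "validate_survey",
]

#: required columns of a long-format survey table
SURVEY_COLUMNS = ["site_id", "year", "species_id", "abundance", "sampled_area", "study_id"]
#: required columns of the site metadata table
SITE_COLUMNS = ["site_id", "ecoregion", "protection", "latitude", "longitude", "study_id"]

PROTECTION_LEVELS = ("MPA", "OA")


class SchemaError(ValueError):
    """A required column is missing or unmappable."""


class ValidationError(ValueError):
    """A row violates a field invariant (negative abundance, bad coordinate, ...)."""


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {', '.join(missing)}")


def read_survey_table(path, schema: dict[str, str] | None = None, sep: str = ",") -> pd.DataFrame:
    """Read a long-format survey CSV into a validated DataFrame.

    Parameters
    ----------
    path : str or file-like
        Delimited text with columns mappable onto site_id, year, species_id,
        abundance, sampled_area, study_id (replicate_id optional).
    schema : dict, optional
        Mapping from file column names to canonical field names.
    sep : str
        Field delimiter, default comma.
    """
    df = pd.read_csv(path, sep=sep, encoding="utf-8")
    if schema:
        df = df.rename(columns=schema)
    _require_columns(df, SURVEY_COLUMNS, "survey table")
    df = df.copy()
    df["year"] = df["year"].astype(int)
    df["abundance"] = pd.to_numeric(df["abundance"])
    df["sampled_area"] = pd.to_numeric(df["sampled_area"])
    bad = df.index[df["abundance"] < 0]
    if len(bad):
        raise ValidationError(f"negative abundance at row(s) {list(bad[:10])}")
    bad = df.index[~(df["sampled_area"] > 0)]
    if len(bad):
        raise ValidationError(f"non-positive sampled_area at row(s) {list(bad[:10])}")
    return df


def read_site_table(path, schema: dict[str, str] | None = None, sep: str = ",") -> pd.DataFrame:
    """Read site metadata (ecoregion, MPA/OA protection, coordinates)."""
    df = pd.read_csv(path, sep=sep, encoding="utf-8")
    if schema:
        df = df.rename(columns=schema)
    _require_columns(df, SITE_COLUMNS, "site table")
    df = df.copy()
    bad = df.index[~df["protection"].isin(PROTECTION_LEVELS)]
    if len(bad):
        raise ValidationError(
            f"protection must be one of {PROTECTION_LEVELS}; bad row(s) {list(bad[:10])}"
        )
    if (df["latitude"].abs() > 90).any():
        raise ValidationError("latitude outside [-90, 90]")
    if (df["longitude"].abs() > 180).any():
        raise ValidationError("longitude outside [-180, 180]")
    return df


def write_survey_table(df: pd.DataFrame, path, sep: str = ",") -> None:
    df.to_csv(path, sep=sep, index=False, encoding="utf-8")


def aggregate_site_year(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicate transects: sum abundance per (site, year, species).

    The total sampled area of a site-year is the sum of its replicate areas
    and is attached to every species row of that site-year.  Idempotent: a
    table that is already one-row-per-(site, year, species) passes through
    unchanged (each site-year then has a single replicate).
    """
    _require_columns(records, SURVEY_COLUMNS, "survey table")
    studies = records.groupby(["site_id", "year"])["study_id"].nunique()
    if (studies > 1).any():
        bad = studies[studies > 1].index[0]
        raise ValidationError(f"site-year {bad} has replicates from multiple study_ids")

    # site-year total area = sum of replicate areas.  A replicate_id column
    # disambiguates replicates; without it, rows of one (site, year, species)
    # are assumed to be distinct replicates, and the site-year total is the
    # largest per-species area sum (the species recorded in the most
    # replicates witnesses the full sampling effort).
    if "replicate_id" in records.columns:
        rep_area = (
            records.groupby(["site_id", "year", "replicate_id"])["sampled_area"]
            .first()
            .groupby(["site_id", "year"])
            .sum()
        )
    else:
        rep_area = (
            records.groupby(["site_id", "year", "species_id"])["sampled_area"]
            .sum()
            .groupby(["site_id", "year"])
            .max()
        )

    out = (
        records.groupby(["site_id", "year", "species_id"], as_index=False)
        .agg(abundance=("abundance", "sum"), study_id=("study_id", "first"))
    )
    out["sampled_area"] = out.set_index(["site_id", "year"]).index.map(rep_area)
    return out[["site_id", "year", "species_id", "abundance", "sampled_area", "study_id"]]


@dataclass
class CommunityMatrix:
    """Years x species abundance matrix of one site."""

    site_id: str
    years: np.ndarray  # strictly increasing ints, length T
    species_ids: list[str]  # length S
    abundance: np.ndarray  # T x S, non-negative

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.abundance = np.asarray(self.abundance, dtype=float)
        if not np.all(np.diff(self.years) > 0):
            raise ValidationError(f"site {self.site_id}: years not strictly increasing")
        if self.abundance.shape != (len(self.years), len(self.species_ids)):
            raise ValidationError(f"site {self.site_id}: abundance shape mismatch")
        if (self.abundance < 0).any() or np.isnan(self.abundance).any():
            raise ValidationError(f"site {self.site_id}: negative or missing abundance")

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def totals(self) -> np.ndarray:
        """Total community abundance per year."""
        return self.abundance.sum(axis=1)


@dataclass
class MetacommunityTensor:
    """Sites x species x matched-years abundance array of one ecoregion.

    Species never observed at a site are structural zeros, so population-level
    sums over sites are well defined.
    """

    ecoregion: str
    site_ids: list[str]
    species_ids: list[str]
    years: np.ndarray  # common matched years, length T
    abundance: np.ndarray  # N x S x T

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.abundance = np.asarray(self.abundance, dtype=float)
        n, s, t = len(self.site_ids), len(self.species_ids), len(self.years)
        if self.abundance.shape != (n, s, t):
            raise ValidationError(f"ecoregion {self.ecoregion}: tensor shape mismatch")
        if (self.abundance < 0).any():
            raise ValidationError(f"ecoregion {self.ecoregion}: negative abundance")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def site_matrix(self, site_id: str) -> CommunityMatrix:
        i = self.site_ids.index(site_id)
        return CommunityMatrix(site_id, self.years, list(self.species_ids), self.abundance[i].T)

    def drop_species(self, j: int) -> "MetacommunityTensor":
        """Leave-one-species-out copy (used by the jackknife)."""
        keep = [k for k in range(len(self.species_ids)) if k != j]
        return MetacommunityTensor(
            self.ecoregion,
            list(self.site_ids),
            [self.species_ids[k] for k in keep],
            self.years,
            self.abundance[:, keep, :],
        )


def build_community_matrices(aggregated: pd.DataFrame) -> dict[str, CommunityMatrix]:
    """Pivot an aggregated survey table into one CommunityMatrix per site.

    Species never seen in a given year at a site get zero abundance (the
    matrix is dense over the site's observed years x species).
    """
    out: dict[str, CommunityMatrix] = {}
    for site_id, grp in aggregated.groupby("site_id"):
        wide = (
            grp.pivot_table(
                index="year", columns="species_id", values="abundance", aggfunc="sum", fill_value=0.0
            )
            .sort_index()
        )
        out[str(site_id)] = CommunityMatrix(
            str(site_id), wide.index.to_numpy(), [str(s) for s in wide.columns], wide.to_numpy()
        )
    return out


def filter_min_years(
    matrices: dict[str, CommunityMatrix], min_years: int = 5
) -> tuple[dict[str, CommunityMatrix], list[str]]:
    """Keep sites observed in at least ``min_years`` years.

    Returns (retained, dropped_site_ids).  An empty retained set is allowed
    (with a warning) — some regions simply lack long series.
    """
    kept = {s: m for s, m in matrices.items() if m.n_years >= min_years}
    dropped = sorted(set(matrices) - set(kept))
    if not kept:
        warnings.warn("no site meets the minimum-years filter", stacklevel=2)
    return kept, dropped


def build_tensor(
    matrices: dict[str, CommunityMatrix],
    years: np.ndarray,
    ecoregion: str = "",
    site_ids: list[str] | None = None,
) -> MetacommunityTensor:
    """Assemble matched site series into a dense N x S x T metacommunity tensor.

    Every site must have been sampled in every requested year; species absent
    from a site are filled with structural zeros.
    """
    years = np.asarray(sorted(set(int(y) for y in years)), dtype=int)
    if site_ids is None:
        site_ids = sorted(matrices)
    species: list[str] = sorted({sp for s in site_ids for sp in matrices[s].species_ids})
    sp_index = {sp: k for k, sp in enumerate(species)}
    arr = np.zeros((len(site_ids), len(species), len(years)))
    for i, s in enumerate(site_ids):
        m = matrices[s]
        year_pos = {int(y): t for t, y in enumerate(m.years)}
        for y in years:
            if int(y) not in year_pos:
                raise ValidationError(f"site {s} lacks matched year {int(y)}")
        rows = [year_pos[int(y)] for y in years]
        for sp_local, sp in enumerate(m.species_ids):
            arr[i, sp_index[sp], :] = m.abundance[rows, sp_local]
    return MetacommunityTensor(ecoregion, list(site_ids), species, years, arr)


@dataclass
class CurationReport:
    n_records: int
    n_sites: int
    n_species: int
    replicate_counts: pd.Series = field(repr=False)
    dropped_sites: list[str] = field(default_factory=list)

    def to_text(self) -> str:
        lines = [
            f"records: {self.n_records}",
            f"sites: {self.n_sites}",
            f"species: {self.n_species}",
            f"sites dropped by min-years filter: {len(self.dropped_sites)}",
        ]
        if self.dropped_sites:
            lines.append("  " + ", ".join(self.dropped_sites))
        return "\n".join(lines)


def validate_survey(
    survey: pd.DataFrame, sites: pd.DataFrame | None = None, min_years: int = 5
) -> CurationReport:
    """Run the curation pipeline and report what it would keep/drop."""
    agg = aggregate_site_year(survey)
    reps = survey.groupby(["site_id", "year"]).size()
    mats = build_community_matrices(agg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kept, dropped = filter_min_years(mats, min_years=min_years)
    if sites is not None:
        unknown = set(agg["site_id"].astype(str)) - set(sites["site_id"].astype(str))
        if unknown:
            warnings.warn(f"sites missing metadata: {sorted(unknown)}", stacklevel=2)
    return CurationReport(
        n_records=len(agg),
        n_sites=len(kept),
        n_species=agg["species_id"].nunique(),
        replicate_counts=reps,
        dropped_sites=dropped,
    )
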