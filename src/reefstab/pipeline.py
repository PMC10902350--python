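"""End-to-end convenience: survey table in, meta-analytic comparison out."""

from __future__ import annotations

import pandas as pd

from . import compare, datamodel
from .meta import MetaResults, RandomEffectsMeta

__all__ = ["curate", "compare_protection"]


def curate(
    survey: pd.DataFrame, min_years: int = 5
) -> tuple[dict[str, datamodel.CommunityMatrix], list[str]]:
    """Aggregate replicates, pivot to per-site matrices, apply the min-years
    filter.  Returns (matrices, dropped_site_ids)."""
    agg = datamodel.aggregate_site_year(survey)
    mats = datamodel.build_community_matrices(agg)
    return datamodel.filter_min_years(mats, min_years=min_years)


def compare_protection(
    survey: pd.DataFrame,
    sites: pd.DataFrame,
    measures: tuple[str, ...] = compare.STABILITY_MEASURES,
    family: str = "gross",
    scale: float | str = "max-mpa-distance",
    distances: pd.DataFrame | None = None,
    iterations: int = 4000,
    burn_in: int = 1000,
    chains: int = 4,
    seed: int = 0,
) -> tuple[dict[str, MetaResults], list[compare.EffectSize], dict[str, str]]:
    """Full MPA-vs-open-area comparison over all ecoregions in one call.

    Curates the survey, derives per-ecoregion jackknifed Hedge's g effect
    sizes for each requested measure, and fits one Bayesian random-effects
    meta-analysis per measure.  Returns (results per measure, effect sizes,
    excluded ecoregions with reasons).
    """
    matrices, _ = curate(survey)
    effects, excluded = compare.metacommunity_effect_sizes(
        matrices, sites, family=family, measures=measures, scale=scale, distances=distances
    )
    results: dict[str, MetaResults] = {}
    for k, measure in enumerate(measures):
        model = RandomEffectsMeta.from_effect_sizes(effects, measure=measure)
        results[measure] = model.fit(
            iterations=iterations, burn_in=burn_in, chains=chains, seed=seed + k
        )
    return results, effects, excluded
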