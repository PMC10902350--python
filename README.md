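# reefstab

Do marine protected areas (MPAs) stabilize reef-fish communities?  `reefstab`
implements the full analysis pipeline for asking that question from
multi-year visual-census surveys: hierarchical partitioning of temporal
stability and asynchrony from site to metacommunity scale, marine-heatwave
quantification from daily SST, trait-based functional richness and thermal
niches, metacommunity network connectivity, and a jackknife + Bayesian
meta-analytic comparison of protected versus open metacommunities.  A
synthetic-data module generates surveys, SST series, traits and effect sizes
with known ground truth, so the whole pipeline is testable end to end
without any data downloads.

It is aimed at quantitative community ecologists working with long-term
reef monitoring data (Reef Life Survey / Reef Check style long-format
abundance tables).

## The measures

Stability is the inverse coefficient of variation of an abundance series.
With μ and σ the temporal mean and standard deviation:

- **alpha stability** `α_i = μ_i/σ_i` of total abundance at site *i*;
- **species stability** `SP_i = (Σ_j (μ_j/μ_i)(σ_j/μ_j))⁻¹ = μ_i/Σ_j σ_j`,
  the inverse abundance-weighted mean species CV;
- at the metacommunity scale the same construction yields **gamma
  stability** `GAS = μ_M/σ_M`, **average alpha stability**
  `AAS = μ_M/Σ_i σ_i`, **average species stability**
  `ASS = μ_M/Σ_i Σ_j σ_j(i)` and **metapopulation stability**
  `MPS = μ_M/Σ_j σ_j` (σ_j of each species' abundance summed over sites).

Asynchrony comes in two families, computed at four hierarchical levels
(among sites, among populations, among species within sites, among
metapopulations):

- **Gross**: `η = −Σ_j w_j · r(A_j, Σ_{k≠j} A_k)`, minus the
  abundance-weighted mean correlation of each component with the sum of the
  others (range [−1, 1], 1 = perfect compensation);
- **Loreau–de Mazancourt**: `1 − φ` with
  `φ = σ²_total/(Σ_j σ_j)²` (range [0, 1]).

The two are linked by exact identities (`α = SP/√φ`, `GAS = AAS/√φ_spatial`)
that the test suite verifies to 1e−10.  Because every measure is a CV, all
are invariant to multiplying abundances by a constant; sampling effort is
therefore controlled downstream with a log-area offset, not by densities.

The MPA-vs-open comparison matches sites on common year windows and within
a spatial scale (the maximum MPA–MPA distance, or a fixed band), derives a
variance for each single-valued measure by leave-one-species-out jackknife,
combines the two conditions into a Hedge's *g*, and pools metacommunities
with the hierarchical model

    y_m ~ Normal(θ_m, σ_m²),  θ_m ~ Normal(μ, τ),
    μ ~ Normal(0, 1),         τ ~ Half-Cauchy(0, 1),

sampled by a conjugate Gibbs sampler (4 chains × 4000 iterations, 1000
burn-in by default) with split-R̂ convergence checks.

Marine heatwaves are detected as runs of at least 5 days with SST above the
seasonally varying 90th-percentile climatological threshold (11-day pooled
window, 31-day smoothed, 1982–2011 baseline); events separated by fewer
than 3 days merge, and intensities are measured relative to the threshold.

## Worked example

```python
from reefstab import ScenarioConfig, simulate_scenario, compare_protection

survey, sites = simulate_scenario(ScenarioConfig(seed=1))   # 2 ecoregions
results, effects, excluded = compare_protection(survey, sites, seed=1)

for e in effects:
    if e.measure == "GAS":
        print(f"{e.metacommunity_id}: g = {e.g:.2f} (var {e.variance:.3f}, "
              f"{e.n_mpa_species} MPA / {e.n_oa_species} OA species)")
print(results["GAS"].summary())
```

prints

```
eco00: g = 1.39 (var 0.165, 15 MPA / 15 OA species)
eco01: g = 1.57 (var 0.175, 15 MPA / 15 OA species)
Random-effects Bayesian meta-analysis
================================================
studies (metacommunities): 2
chains x draws:            4 x 3000
mu posterior mean:          1.1140
mu 66% interval:           [ 0.6659,  1.5890]
mu 95% interval:           [-0.3518,  2.0129]
tau posterior mean:         0.7003
significant (95% CI):      False (none)
R-hat (mu):                 1.0014
ESS (mu):                   2848
```

The two Hedge's *g* values say gamma stability is roughly one and a half
pooled standard deviations higher in the protected condition of each
simulated ecoregion.  `results["GAS"].theta_summary()` gives the
per-metacommunity posterior effects (both significantly positive here);
`results["GAS"].plot_forest()` draws them with 66%/95% bars.  The
population-level μ pools only two metacommunities, so its 95% interval
stays wide and overlaps zero even though both individual effects are
clearly positive — with a dozen metacommunities it tightens accordingly.

The pipeline pieces are also available individually
(`reefstab.stability`, `reefstab.mhw`, `reefstab.traits`,
`reefstab.thermal`, `reefstab.connectivity`, `reefstab.effort`) and through
a thin CLI: `reefstab simulate|validate|stability|mhw|traits|network|meta`.

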