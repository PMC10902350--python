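# Methods

This note documents the models and procedures `reefstab` implements, the
choices made where the design was genuinely open, what the synthetic-data
generator does and does not emulate, and the package's known limitations.

## Data model and curation

The observational unit is a long-format survey record: (site, year,
species, abundance count, sampled area, study id), optionally with a
replicate id.  Curation follows standard practice for multi-program reef
monitoring: replicate transects are collapsed by summing abundance per
(site, year, species), the site-year's total sampled area is the sum of
its replicate areas, and only sites observed in at least five years are
retained.  Years need not be consecutive — the filter counts observation
years, and all temporal statistics treat a series as an ordered sample.
When no replicate id is present, rows of one (site, year, species) are
assumed to be distinct replicates and the site-year area is recovered as
the largest per-species area sum (the species recorded in the most
replicates witnesses the full effort); supplying `replicate_id` removes
the ambiguity.

Metacommunity tensors are dense site × species × year arrays over matched
years; species never observed at a site are structural zeros, which is
what the population-level sums in the metapopulation measures require.

## Stability and asynchrony partitioning

All stability measures are inverse coefficients of variation and all are
computed with the sample standard deviation (n−1 denominator; `ddof` is an
argument where it matters).  The hierarchy is:

| measure | definition |
|---|---|
| alpha stability | μ_i/σ_i of total site abundance |
| species stability | μ_i/Σ_j σ_j(i) (inverse abundance-weighted mean species CV) |
| gamma stability (GAS) | μ_M/σ_M of total metacommunity abundance |
| average alpha stability (AAS) | μ_M/Σ_i σ_i |
| average species stability (ASS) | μ_M/Σ_i Σ_j σ_j(i) |
| metapopulation stability (MPS) | μ_M/Σ_j σ_j of species totals across sites |

ASS is the inverse of the site-abundance-weighted mean of the per-site
weighted species variabilities.  An alternative reading that inverts a
weighted sum of the per-site species *stabilities* is representable in the
test oracles but rejected: it turns ASS into a variability (one site with
one species would give σ/μ instead of μ/σ), breaking both the collapse
identity (one site, one species ⇒ GAS = AAS = ASS = MPS = alpha) and the
ordering chain GAS ≥ AAS ≥ ASS that follows from the subadditivity of the
standard deviation.  The tests document this explicitly.

Gross asynchrony weights each component's correlation with the sum of the
others by relative abundance; the sign is flipped so +1 is perfect
compensation.  At the metacommunity scale the average-species level is the
abundance-weighted mean of site-level Gross asynchronies (the site values
already carry the sign conversion).  The LdM family applies the variance
ratio φ = σ²_total/(Σσ_j)² at each level: spatial (site totals),
metapopulation (species totals), per-species-across-sites
(abundance-weighted over species), and within-site (abundance-weighted
over sites).

Degenerate terms are never silently zeroed: a zero-variance series makes
its correlation undefined, so the term is dropped, the remaining weights
are renormalised to one, and the result is flagged
(`zero-variance-component`).  Whole-measure degeneracies return NaN with a
named flag.  Standard deviations within 1e−12 (relative) of zero are
treated as exact zeros — they arise from constant series under floating
point.  Detrending removes each species' OLS linear trend on year and adds
the mean back, so μ_j is unchanged and σ_j becomes the residual SD; it is
idempotent and clips at zero so abundances stay non-negative.

The cyclic-shift null model rotates every species' series independently by
a uniform offset in {0, …, T−1} (preserving each series' values and
autocorrelation while destroying cross-species phase).  The observed
matrix counts as one realization: with n_iter shifts the two-sided p-value
is the fraction of the n_iter + 1 values at least as far from the combined
mean as the observed one, so the minimum attainable p is 1/(n_iter + 1)
(1/1000 at the default 999 iterations).

## Marine heatwaves

The climatology pools, for each of 366 calendar days, all values within a
±5-day window across the baseline years (1982–2011 by default; shorter
periods are accepted with a warning), takes the mean and the 90th
percentile (linear interpolation between order statistics; the percentile
convention is configurable because event counts are sensitive near ties),
and smooths both with a 31-day circular moving average.  February 29 is
day 60 of a fixed 366-day calendar (March 1 is always day 61) and is
pooled like any other day.  Series with more than 10% missing data in the
baseline are refused unless explicitly overridden; missing days inside a
candidate run break the run rather than being imputed.

Events are maximal runs of at least five consecutive days above the
threshold; two qualifying events separated by at most two sub-threshold
days merge into one event spanning the gap.  Intensities are SST minus the
*threshold* (a flag switches to the climatological-mean convention for
comparison); merged events include their gap days, so the event mean can
be pulled below any single day's intensity while max ≥ mean always holds.
Site-level summaries restrict to event days falling in the years the site
was surveyed; a site with no such days gets zeros with a `no-events` flag
so heatwave intensity stays a defined covariate everywhere.

Note that a noise-free periodic series exceeds its own pooled-window
threshold right at the seasonal peak (the 90th percentile of an 11-day
window around the peak sits below the peak value); this is an artifact of
noise-free input, and the recovery tests select injected events away from
the peak.

## Functional traits and thermal niches

Traits are body size, trophic position, intrinsic vulnerability and
thermal affinity (continuous), gregariousness
(solitary < pairing < schooling) and water position
(benthic < demersal < pelagic-reef < pelagic) as ordinals, and trophic
category (carnivores/grazers/microphages/planktivores) as nominal.
Missing traits are filled with the genus mean (continuous) or genus modal
category (ordinal; ties resolve to the lower category, deterministically),
falling back to family; rows still incomplete are flagged `unresolved`.

Gower dissimilarity scores ordinals by rank position rescaled to [0, 1]
(preserving order without asserting an interval scale), normalises
continuous traits by their pool range, counts nominal mismatches as 0/1,
and averages over the traits observed in both members of a pair; a pair
sharing no observed trait is an error.  Principal-coordinates analysis is
classical metric scaling (double-centre −D²/2, eigendecompose, scale
eigenvectors by √λ).  Negative eigenvalues — expected for non-Euclidean
Gower input — receive no correction and are excluded from the
variance-explained denominator; the first three positive axes are used.
Functional richness of a site is the convex-hull volume of its species'
coordinates divided by the pool hull volume; sites with fewer than four
species or affinely degenerate configurations are undefined (flagged, and
excluded from downstream regressions rather than imputed).  Sample
coverage uses the abundance-based estimator
Ĉ = 1 − (f₁/n)·[(n−1)f₁/((n−1)f₁ + 2f₂)].

A species' temperature index (STI) is the 95th percentile of its
occurrence-location long-term mean SSTs after discarding values outside
the raw distribution's 5th–95th percentile band (at least 10 records by
default).  A site's thermal threshold is the hottest SST attained during
heatwaves over its sampling period — threshold SST plus daily intensity —
which places it on the same °C scale as STI; a bare anomaly convention is
available behind a flag.  With no heatwave during sampling, the fallback
is the maximum climatological threshold over the survey days, flagged
`no-events`.  Species with STI at or above the site threshold are
thermally resistant (boundary inclusive), the rest sensitive; abundances
are summed per site × year × thermal class × trophic category, with
log1p-transformed and z-scored columns appended for smooth-model fitting.
Fitting the smooth models themselves (GAMMs), like the mixed models and
structural equation models at the community scale, is deliberately left to
standard statistics packages — this package prepares their inputs.

## Connectivity

Jaccard dissimilarity (1 − |∩|/|∪|) between site species sets defines a
biological distance; great-circle distance (or a user-supplied by-sea
distance matrix, which takes precedence) a geographic one.  Both are
reduced to minimum spanning trees with deterministic lexicographic
tie-breaking.  Weighted degree is the sum of inverse-distance edge
weights; closeness is the reciprocal mean along-tree path distance, using
edge length = distance so that "close" means geographically near — the
inverse-length variant is available behind a flag since affinity-as-length
is the other defensible convention.  The connectivity test regresses
z-scored biological degree on z-scored geographic closeness with a
two-sided slope test.

## MPA versus open-area comparison

Within each ecoregion, the year-matching algorithm enumerates contiguous
windows (length ≥ 5) of the pooled observed years and keeps the window
retaining the most completely covered sites subject to ≥ 2 MPA and ≥ 2
open sites, breaking ties toward longer windows then earlier starts.
Contiguous windows are a deliberate approximation: exhaustive search over
arbitrary year subsets is exponential and the matching goal — maximise
sites at ≥ 5 shared years — is served by windows.

Spatial matching takes each MPA site as a focal point and collects the
open sites within the scale radius (the maximum MPA–MPA distance by
default, or a fixed 50–100 km band for sensitivity runs).  All MPA sites
fall inside every focal radius at the default scale, so the MPA-side
measures are evaluated once; open-side measures are computed per focal
neighbourhood and averaged (identical neighbourhoods are computed once and
weighted by multiplicity — open sites may legitimately serve several focal
MPAs).

Each measure's variance comes from a leave-one-species-out jackknife:
var = ((S−1)/S)·Σ(θ₍ⱼ₎ − θ̄)², with undefined pseudo-values dropped and S
adjusted.  Hedge's g treats the number of species entering each
condition's jackknife as the group size n, rescales the jackknife
variances to per-observation variances (var·n), pools them as
s_p² = ((n₁−1)v₁n₁ + (n₂−1)v₂n₂)/(n₁+n₂−2), applies the small-sample
correction J = 1 − 3/(4(n₁+n₂) − 9), and reports the large-sample sampling
variance (n₁+n₂)/(n₁n₂) + g²/(2(n₁+n₂)).  These three choices live in one
function (`hedges_g`) so alternatives can be substituted in isolation.

The meta-analysis is a two-level normal model with known study variances,
a Normal(0, 1) prior on the population effect μ and a Half-Cauchy(0, 1)
prior on the between-metacommunity dispersion τ.  Sampling is a fully
conjugate Gibbs sampler — normal updates for θ and μ, inverse-gamma update
for τ² via the auxiliary-variable representation of the half-Cauchy — with
all chains advanced in lockstep as vectorised array updates (4 chains,
4000 iterations, 1000 burn-in by default).  Convergence is summarised by
split-R̂ on μ (required ≈ 1; `converged` uses |R̂ − 1| < 0.05) plus an
effective-sample-size estimate.  Studies with σ_m = 0 pin θ_m = y_m
exactly.  Significance of the population effect uses the central 95%
interval of μ; the per-metacommunity posterior effects θ_m (the
forest-plot quantities, `theta_summary()` / `plot_forest()`) carry their
own 66%/95% intervals.  With very few metacommunities the μ interval is
intentionally conservative: the weak priors let τ absorb any conflict
between a large common effect and the Normal(0, 1) prior, so pooled
significance effectively requires several metacommunities, while the θ_m
intervals remain informative per metacommunity.

## Sampling-effort scaling

Because every measure is a CV, dividing abundances by a constant site-level
area changes nothing; effort is controlled by an offset instead.
Responses and the offset (total sampled area) are log-transformed and
z-scored over the full dataset, and the scaled response is
z(log response) − z(log offset); predictors are z-scored, remoteness
log-transformed first.  A zero-variance offset (single-program data)
z-scores to all zeros, i.e. no adjustment.  The log-response-ratio route
(log response − log area, then z-scored) is provided for comparison; with
equal log-scale variances the two orderings agree exactly, and the tests
check rank concordance under joint lognormal simulation.  Non-positive
values where a log is required become missing, never silently clamped.

## The synthetic-data generator

`simulate_metacommunity` draws species log-abundance series as correlated
Gaussians: an equicorrelation structure at a target pairwise correlation
(the feasibility bound ρ > −1/(S−1) is enforced), optionally with
species-heterogeneous loadings on the shared community factor
(`loading_sd`), species-specific characteristic abundances shared across
sites (`species_mean_sd`, giving the steep abundance distributions of real
fish communities), and a metacommunity-wide regional year effect
(`regional_sd`) with species-specific sensitivities
(`regional_sens_sd`) — a shared environmental driver such as thermal
stress.  Counts are either the rounded exponentiated latent series
(default; closest to the latent variance structure) or lognormal-Poisson
draws (`counts="poisson"`, adding demographic/observation noise that
shrinks relatively as populations grow).  One seed governs a scenario;
per-site substreams are keyed by site index so adding a site leaves
existing series untouched, while species-level draws are keyed at the
metacommunity level because species identities are shared across sites.

`ScenarioConfig` bundles a two-ecoregion study with 12 sites per ecoregion
(half MPA, interspersed with open sites along the transect so protection
is not confounded with position), 15 species, 28-year series and Poisson
counts.  The protection effect has three channels, all mechanisms the
protection literature proposes: MPA abundances are scaled ×3
(`mpa_effect`, which with Poisson counts also damps relative demographic
noise), MPA species fluctuate more independently (pairwise correlation
0.05 versus 0.4 in open areas), and MPA sites feel only 25% of the
regional driver (`mpa_buffering` — protected communities buffered against
region-wide stress).  The regional driver is central to the design: open
sites track it coherently, which depresses their gamma stability through
spatial synchrony, while under the null scenario (no protection effect)
it is common to all sites and cancels in the MPA-minus-open difference.
Under these frozen conditions the effect scenario yields clearly positive,
per-metacommunity-significant effects for all four stability measures, and
null scenarios stay non-significant in well over 90% of seeds.

What the generator does **not** emulate: observation-error models of
visual census (diver effects, detectability), temporal autocorrelation
beyond the regional driver, species colonisation/extinction dynamics,
spatially structured dispersal, or trait–abundance covariation.  Passing
tests on this generator therefore demonstrate the correctness and
calibration of the *estimators* under a known data-generating process, not
robustness to every failure mode of real survey data.

Scale of the shipped problem sizes (two ecoregions, 12 sites, 15 species,
28 years; 200 replicates for meta-analytic coverage; 50 seeds for the null
operating characteristic) is the package's chosen compromise between
Monte-Carlo resolution and quick, single-CPU runs.

## Known limitations

- Mixed-model/SEM/GAMM estimation is out of scope by design; the package
  stops at analysis-ready tables.
- Remoteness and by-sea least-cost distances are accepted as inputs, never
  computed (they require external GIS rasters); great-circle distance is
  the built-in geographic fallback.
- The Hedge's g construction from jackknife variances involves judgement
  (group size, variance rescaling); the chosen reading is isolated in one
  function and documented above.
- The year-matching search is restricted to contiguous windows.
- Percentile and tie conventions (climatology threshold, STI pruning) can
  move event counts and classifications near boundaries; both are
  configurable.
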