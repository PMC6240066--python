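# Methods

This note documents the models, parameter choices and numerical decisions
behind `reef_regimes`, and what the synthetic-data tests do and do not
establish about real survey data.

## The regime model

A reef regime is operationalized as one component of a finite mixture of
multivariate normal distributions over the 10-dimensional functional-group
space (5 benthic covers, 5 fish biomasses), fitted on a transformed scale:
each variable is fourth-root transformed, centred, and standardized to unit
sample SD. The fourth root is strong enough to symmetrize all 10 variables
at once, which is why a single common transform is used. The per-column
centre and scale are recorded (`TransformState`) so that new observations
are mapped with the *training* transform and component means can be
back-transformed exactly ((z·s + c)⁴).

Fitting follows the classic model-based clustering recipe:

- **Initialization** by agglomerative hierarchical clustering cut at K
  groups. Ward linkage on Euclidean distance is used; it is deterministic,
  order-free, and a close stand-in for model-based agglomeration (the exact
  agglomeration criterion is an open choice; BIC selection, not the
  initialization, carries the inferential weight).
- **EM** to a relative log-likelihood tolerance of 1e-6 (max 500
  iterations). Monotonicity of the log-likelihood is checked every fit.
  Non-convergence flags the model rather than raising.
- **Model selection** over K = 1..9 and six covariance structures —
  spherical/diagonal/full crossed with equal/varying across components —
  by BIC = 2·logL − p·log n (larger is better). Six structures span the
  main parameterization axes while keeping the search tractable; the full
  BIC table is reported rather than asserting a single "right" structure.

**Degenerate fits.** Duplicated data points (here, exact zeros produced by
truncation; in real data, true absences) let a mixture component collapse
onto a point mass, sending the likelihood to infinity. Covariances are
therefore floored/ridged during EM (ridge 1e-6·trace/d, variance floor
1e-6·mean variance), and a fit whose final M-step still needs the
floor/ridge is flagged *degenerate* and excluded from BIC selection: the
unbounded "solution" is not a valid maximum-likelihood estimate. Without
this exclusion, BIC rewards spike components with floor variance and
overstates K.

Assignment ties (equal posterior probabilities) break to the lowest
component index, for determinism. Uncertainty is u = 1 − max_k z_ik ∈
[0, 1 − 1/K].

## The synthetic generator

The generator defines the study conditions for every test. Defaults:

- **Components**: K = 5, means equal to the published per-regime
  means of the 10 variables; mixing proportions 205:250:158:200:214
  (n = 1027 total).
- **Spread**: the published values are standard errors; site-level raw SDs
  are SE·√n_regime, mapped to the fourth-root scale by the delta method
  (σ_t ≈ σ_raw·m^(−3/4)/4) with a floor of 0.05 so the two zero-SE cells
  (regime-3 macroalgae, regime-1 predators, both with mean 0) stay proper.
- **Covariance**: diagonal on the transformed scale. The within-regime
  covariance structure is not reported anywhere; diagonal is an assumption,
  and it is also why recovery of the "diagonal-varying" structure by BIC is
  expected rather than remarkable.
- **Truncation**: Gaussian draws on the fourth-root scale are clamped at 0
  before raising to the 4th power (clamping, not rejection, preserves
  seed-reproducibility and speed). Two consequences are worth knowing.
  First, cells with mean 0 acquire a point mass at exactly 0 — realistic
  for absences, and the direct motivation for the degenerate-fit exclusion
  above. Second, the *raw-scale* empirical mean of a component is
  E[t⁴] = μ⁴ + 6μ²σ² + 3σ⁴, which exceeds the nominal μ⁴ noticeably for
  high-variance cells (regime-2 browsers: nominal 20.5 g m⁻², realized
  ≈ 22 after clamping). Component means are therefore always compared on
  the transformed scale or via the fourth power of transformed-scale
  means, which is also how the analysis itself reports them.
- **Benthic covers are not renormalized to 100%** (a Gaussian mixture on
  the transformed scale is incompatible with an exact simplex, and the
  published per-regime row sums are themselves ≈ 98, not 100). A post-hoc
  renormalization switch exists, default off.
- **Surveys**: each profile is decomposed into itemized records. Fish
  biomass per group is split across that group's species (Dirichlet
  shares); an integer count is drawn from the species' typical size and
  the length is back-solved from W = a·TL^b so Σ a·TL^b·count / area
  reproduces the group biomass exactly — this makes the
  generator→harmonization round trip exact to rounding, which the tests
  assert at 1% per cell. A configurable fraction of sites is re-surveyed
  under a second method with counts scaled by a known bias (default 2.0),
  providing the paired calibration subset; schooling-species count
  outliers can be injected at a configurable rate and are flagged.
- **Time series**: per-site first-order Markov chains. The default kernel
  follows the reported row-conditional transition frequencies
  (stay-probabilities 61/93/0/48/83% for regimes 1–5; regime 3 splits
  evenly to 2 and 4; regime 5 never moves to regime 1); unreported cells
  are filled uniformly within the row remainder. Two site-level drivers
  (population-density and thermal-stress proxies, Uniform(0,1), fixed per
  site) shift transition log-odds: row i's logits are
  log k_ij + Σ_d β_d[i,j]·x_d, renormalized; kernel zeros stay zero.
  Default slopes are ±2 on the transitions reported as driver-associated
  (4→5 and 2→2 for population density; 4→4, 5→5, 2→2 and 5→2 for DHW),
  zero elsewhere.
- **Metadata**: depth, complexity and shore-facing direction are drawn
  from the published per-regime summaries; islands are uniform with
  jittered coordinates around island centres. No spatial autocorrelation
  is simulated beyond that jitter.

What passing tests therefore show: the pipeline recovers a known mixture,
known calibration bias, known kernel and known driver slopes *under the
generator's assumptions* (diagonal Gaussian components on the transformed
scale, exact survey decomposition, drivers constant per site). They do not
establish robustness to non-Gaussian within-regime structure, spatially
autocorrelated noise, taxonomic inconsistency, or observation error in the
drivers — none of which the generator emulates.

## Harmonization decisions

- Quantiles are linear-interpolation (type-7) empirical quantiles
  everywhere. Capping is two-step: observations above the global 99.9%
  count quantile flag their species; flagged species' counts above their
  own 99.0% pre-capping quantile are set to that quantile. Re-applying
  with the stored thresholds is a fixed point.
- Calibration decision cascade: a species needs ≥ 10 paired observations;
  pairs > 50% zero (one-sided) trigger the delta form (occurrence ratio ×
  geometric-mean abundance ratio on jointly positive pairs); Shapiro–Wilk
  p < 0.05 on the through-origin linear residuals triggers the log-scale
  (geometric-mean ratio) form. Species failing the rules pool to
  family×trophic, then to a single global method factor. Application
  precedence is species → family×trophic → global, and every fish
  observation must resolve to exactly one scope. Benthic data are never
  calibrated. Island-stratified calibration is honoured only if an island
  column is supplied; otherwise pairs pool across islands.
- Spatial aggregation groups surveys by single-linkage agglomeration on
  great-circle (haversine) distance cut at 300 m — "within 300 m" is
  ambiguous for chains; single linkage is the deterministic, order-free
  reading, so a 250 m + 250 m chain merges even though its ends are 500 m
  apart. Group values are means over member surveys and years; the group
  coordinate is the member centroid.
- Depth-window sensitivity (0–20 m, 5–20 m) is a configuration filter on
  the same code path, not separate code.

## Community statistics

Ordination and dispersion run on the fourth-root (uncentred,
unstandardized) matrix, since Bray–Curtis requires non-negative input.
nMDS is monotone-regression stress minimization (Kruskal stress-1), best
of 50 random starts by default. The dispersion test embeds the
dissimilarity matrix by principal coordinates (keeping negative-eigenvalue
axes and subtracting their squared contribution, clamped at zero),
measures each point's distance to its group *centroid* (not spatial
median), and permutes group labels for the F-statistic null;
p = (1 + #{F_perm ≥ F_obs})/(n_perm + 1) with n_perm = 999 by default. The
centroid statistic agrees exactly with scikit-bio's `permdisp(test=
"centroid")` on Euclidean-embeddable matrices (asserted in tests). ANOVA
and Tukey HSD come from scipy/statsmodels.

## Transition analysis

Yearly site predictions are retained at ≥ 95% membership probability, and
sites need ≥ 3 retained years. Transitions are counted between successive
*retained* years, across gaps (a `consecutive_only` switch restricts to
adjacent years). Per-site-year profiles for prediction are the mean of
that site's surveys in the year. The K×K matrix reports counts,
row-conditional proportions, proportions of the total, and per-cell Wilson
intervals; the Wilson closed form is authored in-package and checked
against statsmodels to 1e-12.

Driver models: for transition i→j, records with regime_t = i give
Bernoulli outcomes 1{regime_t+1 = j}; logit p = α + β·x with the driver
pre-scaled to [0, 1] and α, β ~ Normal(0, 2.5²). Drivers are fitted
separately, and transitions with < 4 occurrences are skipped with an
explicit reason. The posterior is sampled with emcee's affine-invariant
ensemble: 4 independent ensembles of 16 walkers × 1000 steps, first half
discarded, each initialized in a 0.1-SD ball around the MAP. Split R-hat
is computed across the pooled ensembles (individual walkers are too
autocorrelated to serve as chains); well-posed fits reach R-hat < 1.01.

## Problem sizes and runtimes

The test and acceptance workloads use the study-scale n = 1027 for the
mixture fit (≈ 5 s for all 54 K×structure fits), 200 replicates × 999
permutations for dispersion type-I calibration, 40 replicates for
driver-model coverage, and 300 sites × 8 years for kernel recovery. The
ordination script subsamples 300 sites for nMDS (50 starts); stress on the
full matrix is similar but slower to compute.

## Known limitations

- The mixture is fitted on standardized fourth-root data; regimes are
  therefore scale-dependent summaries, not biological entities.
- BIC selection among six structures does not include the full set of
  rotation-constrained parameterizations some model-based clustering
  software searches.
- The delta-method SD mapping is a first-order approximation and is
  noticeably rough for high-variance cells (raw SD ≳ mean); the generator
  inherits that roughness by construction.
- emcee walkers within one ensemble are not independent chains; R-hat is
  computed across independent ensembles, which is conservative but not a
  guarantee of convergence.
- Coral species richness/composition summaries use per-aggregated-site
  cover; per-survey denominators would differ.
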