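# reef-regimes

Coral reefs do not sit on a single axis from coral-dominated to
macroalgae-dominated. When fish and benthic assemblages are considered
together, reef communities occupy a handful of recurring configurations —
*regimes* — and individual reefs move among them over time. This package
implements that analysis as a reusable, tested pipeline for quantitative
community ecologists:

1. **Harmonization** — heterogeneous fish and benthic survey records
   (multiple programs, multiple methods) are converted into one
   analysis-ready matrix of 10 functional groups per site: percent cover of
   coral, macroalgae, turf algae, crustose coralline algae (CCA) and other
   benthic cover, plus biomass (g m⁻²) of browsers, grazers, scrapers,
   predators and secondary consumers. Steps: species exclusions, extreme
   schooling-count capping, allometric biomass *W = a·TL^b*, multiplicative
   method calibration with a species → family×trophic → global decision
   cascade, and 300 m spatial aggregation.
2. **Regime identification** — model-based clustering: the transformed
   site × 10 matrix is fitted with multivariate Gaussian mixtures
   (hierarchical initialization, EM, six covariance structures ×
   K = 1..9), and the number of regimes and covariance structure are chosen
   by BIC (convention BIC = 2·logL − p·log n, larger is better). Each site
   gets membership probabilities z_ik and an assignment uncertainty
   u_i = 1 − max_k z_ik.
3. **Community statistics** — Bray–Curtis nMDS ordination, homogeneity of
   multivariate group dispersions (permutation test), ANOVA + Tukey HSD
   contrasts, and island / shore-direction / coral-composition summaries.
4. **Transitions** — per-site yearly regime predictions (≥ 95% membership
   probability, ≥ 3 years per site) feed K×K transition matrices with
   Wilson binomial intervals, and Bayesian binomial models
   (logit p = α + β·x, Normal(0, 2.5²) priors, MCMC) relate each
   transition's probability to scaled human-population-density and
   thermal-stress (DHW) drivers.

A synthetic-data generator with known ground truth (`reef_regimes.synthetic`)
emulates the statistical structure of the Hawaiian forereef dataset the
method was developed on — a five-component mixture on the fourth-root scale,
itemized survey records that harmonize back to their generating profiles,
paired-method calibration subsets with planted bias, and Markov-chain site
revisits with driver-dependent transition odds — so every stage is testable
offline against truth.

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic
data and write their tables under `results/`:

```bash
python analysis/01_simulate.py      # surveys + time series, ground truth
python analysis/02_harmonize.py     # -> results/profiles.csv
python analysis/03_fit_regimes.py   # -> model, BIC table, assignments
python analysis/04_community_stats.py
python analysis/05_transitions.py
```

`03_fit_regimes.py` prints (seed 1):

```
selected K = 5, covariance structure 'diagonal-varying', BIC = -25598
regime sizes: [194, 142, 227, 270, 189]
mean assignment uncertainty: 0.055
back-transformed component means (raw scale):
 regime  coral  macroalgae  turf  cca  other_cover  browsers  grazers  scrapers  predators  secondary_consumers
      1    5.7         9.7  65.9  3.6         14.3       1.2      4.7       1.5        0.0                  7.9
      2   23.5         0.0  60.1  6.7          5.1       3.9     17.3      11.4        7.1                 23.1
      3   30.2         6.3  42.3  8.3         10.2       3.7     12.1      10.2        3.7                 19.4
      4    9.5        10.0  65.4  8.0          5.7      21.6     21.7      14.5       10.7                 26.5
      5   21.2        13.1  31.9  5.4         22.6       2.7     14.8      10.9        8.8                 29.6
```

BIC recovers the five generating regimes with the generating
(diagonal, per-component) covariance structure. Component labels are
arbitrary; matching on composition, row 1 is the degraded regime (low
coral, low fish, predators absent), row 4 is the low-coral / high-fish
regime (browsers 21.6 g m⁻²), row 3 the highest-coral regime (30.2%
cover), and rows 2 and 5 the remaining coral regimes (macroalgae-free and
mixed-benthos respectively). `05_transitions.py` then recovers the planted
driver effects, e.g. the planted +2 log-odds population-density slope on
the "coral regime gains coral" transition is estimated at
β = 2.07 [1.43, 2.73].

In short library form:

```python
from reef_regimes import GeneratorConfig, generate_profiles, transform
from reef_regimes.regimes import select_model, assign_regimes, regime_means_raw

profiles, truth = generate_profiles(GeneratorConfig(seed=1))
X, state = transform(profiles)
model, bic_table = select_model(X)      # K = 1..9, six structures
assignments = assign_regimes(model, X)  # probabilities + uncertainty
means = regime_means_raw(model, state)  # raw % and g m^-2 scales
```

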