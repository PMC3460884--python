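# Methods

## The forecasting problem

Given binary occurrence records of many species on a regular grid and a
small set of bioclimatic predictors, the package forecasts each species'
climatically suitable range under current and mid-century climates,
combines many imperfect models into a consensus, and summarises what the
forecasts agree and disagree about at the assemblage level.  The design
follows the ensemble-forecasting tradition in species distribution
modelling (SDM): no single model family or climate realisation is
trusted; instead a factorial of projections is built and weighted by
each model's measured skill.

## Predictors

Four bioclimatic variables, in WorldClim naming and units:

| variable | meaning | construction |
|---|---|---|
| bio1 | annual mean temperature (°C) | mean of 12 monthly means |
| bio4 | temperature seasonality | population SD of the 12 monthly means × 100 |
| bio12 | annual precipitation (mm) | sum of 12 monthly totals |
| bio15 | precipitation seasonality | CV of monthly totals, as percent (100 × SD/mean) |

Population (n) rather than sample (n−1) SD is the default, matching the
WorldClim bio4/bio15 convention; `ddof=1` and a raw-ratio CV are
exposed as switches.  A cell whose monthly precipitation is identically
zero has an undefined CV; such cells are masked out of the domain rather
than silently imputed.

## Synthetic study systems

`ensemblesdm.synthetic` generates everything a run needs, with known
truth retained for validation:

* **Monthly climate fields.**  Each driver (annual-mean temperature,
  seasonal temperature amplitude, annual precipitation, wet-season
  concentration) is a smooth gradient plus low-pass-filtered Gaussian
  noise (uniform smoothing kernel, default radius 3 cells).  The four
  drivers are deliberately given *different* spatial orientations
  (latitudinal, longitudinal, diagonal, anti-diagonal) so the four
  derived predictors are identifiable rather than collinear along one
  gradient — with a single shared gradient a fitted model cannot tell
  which variable the species actually responds to, and a planted climate
  shift becomes undetectable in principle.  Future fields add a uniform
  warming delta to every monthly temperature and scale precipitation by
  a factor, one (delta, factor) pair per climate model × scenario.  The
  defaults emulate mid-century AOGCM spreads: deltas of 1.8–3.75 °C
  (pessimistic scenarios 25% above the model's base warming, optimistic
  10% below) with mild drying (factor 1 − 0.04 × delta).
* **Virtual species.**  Suitability is a product of independent
  Gaussians, S(x) = s·exp(−Σₖ(xₖ−μₖ)²/2σₖ²), with optima drawn inside
  the central 10–90% band of each predictor, breadths 12–30% of the
  predictor's observed range, and a maximum suitability s ∈ [0.7, 1].
  Presence is sampled Bernoulli(S) per cell; a species with fewer than
  10 presences (the protocol's minimum) or no absences is redrawn up to
  a retry cap.  The product-Gaussian form keeps the truth analytically
  known, at the price of excluding niche interactions.
* **Land use.**  Paired native/anthropic rasters at finer resolution
  (default 5×5 fine cells per grid cell).  Conversion between the two
  dates removes a stated fraction of native cells, preferentially where
  a known logistic function of three covariates is high
  (Gumbel-perturbed ranking, temperature 0.3, so the preference is
  strong but not a hard threshold, which keeps the planted function
  recoverable by a classifier).

What the generator does **not** emulate: spatially structured sampling
bias, dispersal limits, biotic interactions, non-Gaussian or interacting
niches, realistic GCM spatial anomaly patterns, and geodesic cell areas
(the grid is treated as regular lat/lon).  Passing tests therefore show
that the *pipeline machinery* recovers known truth under its own
assumptions, not that any real fauna's forecasts are accurate.

## Model fitting and evaluation

Per species, presences and absences are split independently 75/25 into
calibration/validation (round-half-up per class, so calibration
prevalence matches observed prevalence to within one record), repeated
k = 10 times.  Six model families are fitted per repeat:

| tag | implementation | defaults |
|---|---|---|
| GLM | logistic regression, no penalty | — |
| GAM | additive spline-basis logistic model (per-predictor cubic B-splines with linear extrapolation + ridge-logistic fit) | 5 quantile knots, C = 1 |
| MARS | native hinge-basis regression: greedy forward pairs, GCV backward prune, logistic refit | ≤ 21 terms, penalty 3 |
| RF | random forest | 500 trees |
| ANN | one-hidden-layer perceptron on standardised inputs | 8 units |
| GBM | gradient boosting | 1000 trees, depth 3, shrinkage 0.01 |

All hyperparameters are overridable per method.  Scores are clipped to
[0, 1].  At projection time each predictor is clamped to its calibration
range (the MaxEnt convention): beyond the conditions a model has seen,
its response is held at the range edge rather than extrapolated freely —
without this, linear and spline logits explode on novel climates and a
single confident wrong-way layer can dominate a consensus.  Clamping is
per fitted model and can be disabled.

Continuous scores are binarised at the ROC threshold maximising
sensitivity + specificity, searched over the distinct score values plus
one value above the maximum (exact optimum, no lattice discretisation);
ties take the smallest qualifying threshold and the rule is
score ≥ t ⇒ presence.  Skill is the True Skill Statistic,
TSS = sensitivity + specificity − 1 ∈ [−1, 1].

**Where the threshold is found.**  The default is the validation scores
(threshold and reported TSS from the same held-out repeat, the
biomod2/dismo convention).  Thresholding on calibration scores is
available (`threshold_on="calibration"`) but is not the default for a
measured reason: tree ensembles reproduce their training labels almost
exactly, so their calibration ROC threshold sits near the top of the
score scale, far above their honest out-of-sample probabilities, and
validation sensitivity collapses toward zero.  Validation thresholding
trades a small optimistic bias in the reported TSS for thresholds that
are meaningful for every model family.

## Ensemble consensus

Each calibrated model is projected onto every climate: 6 methods × 10
repeats = 60 binary layers for the current climate and 6 × 4 climate
models × 10 = 240 layers per emission scenario for the future.  The
consensus frequency is W = Σ wⱼbⱼ / Σ wⱼ with wⱼ = max(TSSⱼ, 0): each
layer is weighted by its own repeat's skill (a per-method mean weight
and a group-by-method two-stage consensus are config options), and
worse-than-random layers are excluded rather than allowed to subtract
evidence.  A cell is a consensus presence when W ≥ 0.5 — inclusively —
and the continuous W is retained alongside the binary call.  Scenario
maps are combined by the per-cell median of W, re-binarised at 0.5.  A
species whose layers are *all* worse than random is an explicit error
at the headline consensus; sub-ensembles assembled purely for
bookkeeping (one method's repeats inside the factorial summary) fall
back to the unweighted frequency instead of aborting the run.

## Assemblage metrics

With SR the current per-cell richness, G species gained, L species lost
between timeframes:

* turnover T = (G + L)/(SR + G) ∈ [0, 1], defined as 0 when SR + G = 0
  (no community, no change); L > SR is rejected as impossible;
* retention = 100·|current ∩ future| / |current|, masked (not zero)
  where a cell currently holds no species.  An alternative additive
  reading, 100·(|current| + |current ∩ future|)/|current|, is exposed
  behind `retention_formula="additive"`; it is ≥ 100 by construction
  and kept only for comparison because the verbal definition of the
  metric admits both readings;
* per-species climate-space change: lost% and gained% relative to the
  current range, summarised across species by the median and the
  semi-interquartile range (Q3 − Q1)/2 with linear-interpolation
  quartiles.

The mean-turnover surface averages per-cell turnover across the
method × climate-model × scenario factorial, each combination using its
own within-combination consensus (consensus over the 10 repeats);
repeats are treated as sampling noise, not a forecast factor.

## Uncertainty partition

Per cell, consensus richness forms a complete 6 × 4 × 2 factorial with
one observation per (method, climate model, scenario) and no
replication.  Main-effect sums of squares come from marginal means
against the grand mean; everything else (all interactions) is the
residual.  Scenario is a third crossed main effect by default; a
two-way-per-scenario mode (SS summed over the two scenario slices) is
provided because the original two-factor protocol generalises to three
factors in more than one way.  The per-cell total SS as a percent of
the summed total maps where forecasts disagree; pooled factor SS over
cells attributes the disagreement.  Factors left with a single level
are dropped from the design; if every forecast agrees everywhere the
attribution is empty rather than 0/0.

## Land conversion and habitat filtering

A native/anthropic transition matrix is estimated by class counts
between two dates.  The Markov chain fixes the *quantity* of change per
step (expected converted count = native count × P[N→A], rounded half
up); *allocation* converts the highest-suitability native cells first
(deterministic, ties by cell id; a seeded stochastic mode samples
proportionally to suitability).  Conversion suitability reuses the
shared classifier interface (default GLM) on covariates of
native-at-first-date cells.  The default horizon is 7 steps of the
estimated interval (a ~6-year observation interval stepped to
mid-century); annualising the matrix instead is a config choice left to
the user.  Habitat filtering removes a coarse cell's consensus
presences when the fraction of its fine cells still native falls below
`min_native_fraction` (default 0.5); the rule guarantees filtered
richness ≤ unfiltered richness everywhere.

## Determinism and numerics

One master seed is fanned out into named streams (SeedSequence keyed by
stage/species/method/repeat), so adding a species or method never
perturbs other results, and two runs under one seed write byte-identical
surfaces and manifests.  SS identities are exact to ~1e-9; the ROC
search is exact over observed scores; round-half-up is used wherever
the protocol rounds counts.  The run-location directory is excluded
from the recorded config so artefacts are byte-comparable across
locations.

## Problem sizes

The default configuration — 20 × 20 grid, 5 virtual species, 6 methods,
4 climate models, 2 scenarios, 10 repeats — was chosen so a complete
run (300 model fits, 2,700 projection layers) finishes in a few minutes
on a single core while every factorial dimension of the protocol is
exercised at full size.  Recovery experiments use 12 species on a
28 × 28 grid — enough species that proportion-based checks (e.g. sign
agreement across species) are not all-or-nothing, and enough cells that
each species has the occurrences needed to constrain all four response
curves — with a uniform planted shift (+2.5 °C, 18% drying, identical
across climate models and scenarios) chosen transverse to the climate
manifold so every species' true range changes decisively.  Grids and
species counts scale up linearly in cost.

## Known limitations

* Equal-area phrasing vs lat/lon grids is not reconciled; no area
  weighting is applied anywhere.
* No pseudo-absence machinery or presence-only methods; absences are
  assumed observed.
* The additive-MARS learner is degree-1 (no hinge interactions).
* The land-change stage is a deliberate simplification of
  transition-potential modelling suites (no road/city networks, no
  multi-class transitions, no validation back-cast).
* Per-species *direction* of forecast range change is materially less
  reliable than range overlap: with tens of Bernoulli-sampled presences
  the models identify the temperature axis of a niche far better than
  the precipitation axis, so precipitation-driven contractions are often
  forecast as relocation or mild expansion.  Consensus maps recover
  *where* species are (median Jaccard ≈ 0.77 against planted truth);
  per-species change signs agree with truth for only about two-thirds of
  species in the recovery experiment.
* Recovery results certify the machinery under the generator's
  assumptions only; real-data performance depends on sampling bias,
  niche complexity and climate-model realism that the generator does
  not emulate.
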