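# ensemblesdm

Ensemble forecasting of species distributions under climate change, as a
tested, reusable Python pipeline.

Biogeographers forecasting where species will find suitable climate face
two compounding sources of arbitrariness: the choice of statistical
model and the choice of future-climate realisation.  The ensemble
approach embraces both — fit *many* models, project them onto *many*
climates, and keep only what they agree on, weighting each projection by
its measured skill.  `ensemblesdm` implements that protocol end to end:

* **Occurrence models** — six families (GLM, GAM, MARS, random forest,
  neural network, gradient boosting) fitted per species under 10
  repeated stratified 75/25 cross-validation splits that maintain the
  observed prevalence.
* **Skill and thresholds** — continuous scores binarised at the ROC
  threshold maximising sensitivity + specificity; skill measured by the
  True Skill Statistic, TSS = sensitivity + specificity − 1 (+1 perfect,
  ≤ 0 no better than random).
* **Consensus maps** — per species, 6 × 10 = 60 current layers and
  6 methods × 4 climate models × 10 repeats = 240 future layers per
  emission scenario, combined into a TSS-weighted projection frequency
  W; presence where W ≥ 50%, the continuous W retained alongside.
* **Assemblage metrics** — richness, temporal turnover
  T = (G + L)/(SR + G), percent of species retaining suitable climate
  per cell, and per-species climate-space loss/gain with median and
  interquartile-deviation summaries.
* **Uncertainty partition** — per-cell ANOVA without replication of
  consensus richness over the method × climate-model × scenario
  factorial: where the forecasts disagree, and which factor is to blame.
* **Land conversion** — a Markov transition matrix between native and
  anthropic land, suitability-driven spatial allocation, and habitat
  filtering of the consensus maps by remaining native habitat.
* **Virtual species** — a synthetic-data module generating gridded
  monthly climates, species with known Gaussian niches, and paired
  land-use rasters, so the entire pipeline is validated against planted
  truth without any downloads.

## Worked example

Fit all six model families on one virtual species and report held-out
skill (`examples/02_fit_and_evaluate.py`):

```text
species sp01: 14 presences on 400 cells

        threshold    tss
method
ANN         0.071  0.742
GAM         0.060  0.804
GBM         0.004  0.608
GLM         0.031  0.519
MARS        0.058  0.650
RF          0.038  0.617
```

Each row is a method's mean ROC threshold and mean validation TSS over
5 repeats: every family beats chance (TSS 0), the smoothers doing best
on this species' Gaussian niche, and those TSS values become the
weights of that method's layers in the consensus.

Partition forecast disagreement (`examples/04_uncertainty_partition.py`):

```text
2x2 worked example [[1,2],[3,4]]:
  SS_rows     = 4.0
  SS_cols     = 1.0
  SS_residual = 0.0
  SS_total    = 5.0

pooled attribution of forecast-richness variation (percent):
  method           76.9
  climate_model     2.3
  scenario          4.8
  residual         16.0
```

The choice of modelling method dominates disagreement among
projections, with climate model and emission scenario far behind — the
ranking this style of analysis typically reports.

The other scripts in `examples/` cover the synthetic study system,
consensus forecasting and range change, land conversion, and a full
deterministic pipeline run.  There is also a thin CLI:

```sh
ensemblesdm run-all --seed 1 --outdir run1
```

## Layout

```
src/ensemblesdm/
  grid.py        grid/raster model, range-polygon overlay, CSV/ASCII I/O
  synthetic.py   climates, virtual species, land-use pairs (known truth)
  sdm.py         cross-validation, six model families, ROC + TSS
  ensemble.py    projection stacks, TSS-weighted consensus
  metrics.py     richness, turnover, retention, range change
  uncertainty.py ANOVA without replication, uncertainty surfaces
  landuse.py     Markov land change, habitat filtering
  pipeline.py    RunConfig, validation, end-to-end orchestration
  cli.py         thin click front end
docs/methods.md  model assumptions, defaults, design choices, limits
```
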