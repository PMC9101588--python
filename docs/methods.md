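# Methods

This note documents the models, statistics, defaults and design choices in
`esdm`, and what the synthetic validation does and does not demonstrate.

## Problem setting and model

The package addresses presence-only distribution modelling of rare species on
a regular lon/lat grid (the intended resolution is 30 arc-seconds, ~0.9 km).
The unit of analysis is the grid cell. For species *i* with presence cells
P_i, the pipeline constructs a binary classification problem:

* **labels**: 1 for each presence cell, 0 for each pseudo-absence cell;
* **pseudo-absences**: `round(2 × |P_i|)` cells drawn uniformly without
  replacement from the valid, non-presence cells of the study region. They
  are drawn once per species and reused across evaluation replicates, so
  replicate variation reflects the train/test partition only.
* **design matrix**: continuous covariates as-is; the categorical land-cover
  layer one-hot encoded with an encoding fixed per species dataset. Rows are
  canonically ordered by (row, col, label) so assembly is independent of
  record order.

Nine families are fitted behind a uniform probability-of-presence contract
(GLM, SVM, RF, BRT, MARS, MAXENT, CART, FDA, MDA; see below), evaluated on
100 stratified 80/20 random partitions, and combined as a weighted average

  p(x) = Σ_f w_f p_f(x),  w_f ∝ max(0, mean over replicates of TSS*_f),

where TSS*_f is family *f*'s test TSS at its optimal threshold. Weighting by
TSS rather than raw (sensitivity + specificity) means a no-skill family
(sens + spec ≈ 1) receives weight ≈ 0 instead of a constant share; the raw
mode remains available via `weight_statistic="sens_spec"`.

The species-level threshold is the weighted average of per-family mean
optimal thresholds; cells with ensemble prediction strictly greater than it
are predicted presences. Per-species binary maps are summed cellwise into a
richness map; a cell is nodata only where every input map is nodata, and the
per-cell count of contributing species is recorded. An optional stream
buffer keeps only cells whose centers lie within a given distance (default
2 km) of a stream network.

## Evaluation statistics

All metrics use the rule `score > threshold ⇒ presence`.

* **AUC** is the Mann–Whitney statistic `(#(pos > neg) + ½#(ties)) / (n₊ n₋)`,
  identical to the trapezoidal area under the ROC built from the unique score
  values plus sentinels beyond both extremes.
* **TSS** = sensitivity + specificity − 1, computed at the optimal threshold.
  It ranges over [−1, 1]; negative values are possible and are not clipped,
  since the standard formula is the only computable definition.
* **Optimal threshold** maximizes sensitivity + specificity over the ROC
  candidate set; ties break toward the lowest such threshold, which favours
  sensitivity — the conservative direction for conservation screening.
* **Deviance** is the mean binomial deviance −2·mean(y ln p + (1−y) ln(1−p)),
  with p clipped to [1e-10, 1 − 1e-10]. Different modelling toolkits scale
  deviance differently (per-observation vs. summed, family-specific
  normalizations), so deviances are comparable within this package but not
  across toolkits.
* **Permutation importance** of covariate j (a one-hot group permuted as a
  unit): over `n_permutations` shuffles, the mean of
  100·max(0, (AUC − AUC_perm)/AUC) and of 100·(1 − r), where r is the Pearson
  correlation between original and permuted predictions (Spearman behind
  `method="spearman"`). Importance is evaluated on the full species dataset
  with the refitted ensemble; other columns are left untouched during a
  permutation rather than being fixed at their means — permuting one column
  is the standard, model-agnostic formulation.

## Replicate design

"100 bootstrap replicates" is implemented as 100 independent random 80/20
partitions (repeated subsampling), not with-replacement resampling of the
training set: test sets stay disjoint from training within every replicate,
which keeps the test metrics honest at n as small as 30. A literal
with-replacement mode exists behind `with_replacement=True` (the test
partition stays disjoint either way). Partitions are stratified by class
with largest-remainder allocation, keeping train-set class proportions
within one member of the global proportions and guaranteeing both classes in
both portions — without stratification, single-class test sets (AUC/TSS
undefined) are common at 10 presences.

## Base families and defaults

Standard scikit-learn / LightGBM estimators stand behind the contract; the
feature constructions and the ensemble logic are the package's own.

| family | implementation | notable defaults |
|---|---|---|
| GLM | logistic regression, linear + quadratic terms for continuous covariates | effectively unpenalized (C = 1e6) |
| SVM | RBF SVC, Platt-scaled (sigmoid calibration, 3-fold) | C = 1, gamma = "scale" |
| RF | random forest, class-frequency votes | 100 trees |
| BRT | gradient-boosted trees (LightGBM) | lr 0.01, ≤500 trees, early stop on held-out deviance (20% stratified validation split, patience 10); min usable n = 20 |
| MARS | two-sided hinge basis (3 quantile knots per covariate) + logistic link | C = 1 |
| MAXENT | L1 logistic on linear + quadratic + hinge features, presences vs. pseudo-absence background | C = 1 |
| CART | depth-limited tree, leaf class frequencies | max depth 5, min leaf 2 |
| FDA | LDA on the quadratic basis | — |
| MDA | per-class Gaussian mixtures, Bayes posterior | ≤2 full-covariance components per class, capped at ⌊n_class/5⌋; reg_covar 1e-2 |

Forest size is 100 trees rather than a larger count: at the sample sizes this
pipeline targets (n ≤ ~150 rows) test AUC is indistinguishable from much
larger forests while keeping a full 9-family × 100-replicate × 20-seed
validation run in the minutes range on a single CPU. BRT's minimum usable
sample size of 20 reflects that boosting with an internal validation split
cannot be estimated sensibly below that; smaller datasets raise a structured
`FitError` and the family is simply absent from that species' ensemble.

Any family whose fit fails on a replicate is recorded and excluded from that
replicate; a family failing all replicates is excluded from the ensemble with
its failure cause kept in the results. Final ensemble members are refitted
on the full species dataset (`refit="full"`), using all data for the
published map; `refit="replicate"` keeps a replicate model instead.

## Covariate preparation

* **Percent slope** from elevation: Horn's 3×3 third-order finite
  differences, `100·sqrt((dz/dx)² + (dz/dy)²)`, with per-latitude conversion
  of cell size from degrees to meters (truncated spherical-harmonic series
  for meters per degree). Edges are handled by linear-extrapolation padding,
  equivalent to one-sided differences and exact for planar ramps; nodata
  neighbours fall back to the centre value and the output is nodata exactly
  where elevation is.
* **Collinearity screen**: pairwise Pearson |r| over all valid cells of the
  study region (covariates are screened before any species-specific
  sampling). Pairs are visited in descending |r| and the layer later in the
  user-supplied order is dropped, then correlations are recomputed — a
  deterministic rule that lets users protect preferred layers by ordering
  them first. Categorical layers are exempt. Zero-variance layers are
  dropped up front with a warning. Default threshold 0.8.
* **Grid conventions**: WGS84 lon/lat, north-up, 0-based (row, col),
  half-open cells `[edge, edge + cell_size)`; a point on an interior edge
  belongs to the east/south cell. Rasters are read and written as
  single-band ESRI ASCII grids (text); region and stream geometry as GeoJSON.
* **Stream buffer** distance uses an equirectangular approximation anchored
  at the grid centre — at 2 km buffers the approximation error is orders of
  magnitude below a cell width.

## Synthetic data: what it emulates and what it does not

The generator produces a 120×120 grid (the 30 arc-second cell size of the
intended application) with k = 6 independent continuous covariates as
Gaussian random fields smoothed to a correlation length of 8 cells and
standardized to mean 0, sd 1, plus one 4-class categorical layer cut from a
further smoothed field. Virtual species have logistic responses
`logistic(β₀ + Σ βⱼ xⱼ)` with β₀ calibrated by root-finding so that mean
suitability over valid cells hits a target prevalence within 0.01
(default **0.10** — the restricted-range regime typical of the rare,
stream-associated taxa this pipeline targets; a species occupying a quarter
of a basin would not be a realistic validation subject, and high prevalence
also mechanically caps attainable AUC near 1 − prevalence/2 because uniform
pseudo-absences then often fall in fully suitable habitat). A unimodal
(`response="gaussian"`) mode exists for realism; the default is monotone
logistic because that is the simplest truth the importance machinery must
recover. Presence records are drawn without replacement with probability
proportional to true suitability, jittered within their cells, with optional
duplicate records to exercise deduplication; defaults span the 10–43 unique
cells per species of the intended use.

The recovery experiment runs the full pipeline on single-driver species
(|β| = 6, 40 presences, 100 replicates, nine families) and reports ensemble
test AUC/TSS, whether the top-importance covariate is the true driver, and
the mean absolute richness error against truth maps binarized at
suitability > 0.5. A permuted-label null run checks every family scores
near AUC 0.5.

What passing these checks shows: the sampling, fitting, evaluation,
weighting, thresholding and stacking machinery is internally correct and can
recover a known monotone signal at realistic sample sizes. What it does not
show: performance on real field data — the generator has no spatial sampling
bias (records are suitability-proportional, field surveys are
accessibility-biased), no detection error, no covariate measurement error,
independent covariates (real bioclim layers are strongly collinear), and a
correctly specified response family.

## Numerical choices and degenerate inputs

* Probabilities are clipped to [0, 1] after prediction; deviance clips at
  1e-10. Grid geometries must agree to 1e-9 degrees to be combinable.
* All randomness flows from integer seeds through `numpy.random.default_rng`;
  the pipeline derives per-species seeds by hashing the species name with the
  master seed (stable across runs and execution order), and replicate/family
  offsets from those. Two runs with identical config and seed write
  byte-identical CSVs.
* Ties at the optimal threshold break low; ties in AUC count one half.
* A species dataset with overlapping presence/pseudo-absence sets, a split
  request with a class of fewer than two members, an all-nodata elevation
  layer, an empty stream geometry, or insufficient background cells each
  raise immediately with a message naming the offender.
* Zero-variance predictions give zero importance with a warning rather than
  NaN.

## Known limitations

* Pseudo-absences are uniform background; target-group or environmentally
  stratified schemes are out of scope.
* No reprojection: all inputs must already share one lon/lat grid.
* Richness stacking is hard (binary) stacking; probability-sum stacking and
  cross-member uncertainty maps are not provided.
* TSS-weighted averaging is the only combination rule; no model selection or
  stacked regression combiners.
* The per-species threshold averages family thresholds rather than
  re-optimizing on ensemble scores — the published-map convention this
  package follows; both quantities are available in the results object if a
  user prefers to re-threshold.
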