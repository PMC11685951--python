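# Methods

## Problem and model

`srscape` builds *isoscapes* of bioavailable strontium — gridded maps of
the ⁸⁷Sr/⁸⁶Sr ratio entering food webs from the substrate — and uses them
to infer the geographic origin of individuals from tissue isotope values.
⁸⁷Sr/⁸⁶Sr varies with bedrock age and composition (⁸⁷Rb decay makes old,
Rb-rich terranes radiogenic), modulated by atmospheric inputs such as
aeolian dust and sea salt, so it can be predicted from environmental
covariates.

The mean surface is a bagged regression-tree ensemble (random-forest
regression). Each of B trees is grown on a bootstrap resample (n draws of
n with replacement) of the georeferenced sample table, on a design matrix
of continuous and one-hot-encoded categorical predictors; the per-cell
prediction μ_c is the average of the per-tree predictions t_b(x_c).
Out-of-bag (OOB) predictions — averaging only trees that never drew a
sample — provide honest R²/RMSE without a holdout. Per-tree in-bag counts
N_{b,i} are retained because the uncertainty estimator needs them.

Co-located samples are deliberately **not** aggregated: several
measurements in one grid cell are kept as independent rows, so the
within-cell scatter of ⁸⁷Sr/⁸⁶Sr among substrates becomes part of what
the ensemble learns, instead of being collapsed into a cell median.

## Prediction uncertainty

Per-cell standard errors use the infinitesimal jackknife for bagging:

    V_raw(x) = Σ_i Cov_b[N_{b,i}, t_b(x)]²,

with the empirical covariance over trees normalised by 1/B (population
form). Finite B inflates V_raw, so a bias correction
(n/B²)·Σ_b (t_b − t̄)² is subtracted (on by default, switchable) and the
result truncated at zero; truncation events are counted. For small
ensembles the correction can overshoot — a three-tree worked fixture in
the tests shows a raw variance of 1/9 truncating to 0 — which is why
assignments should normally carry a non-zero `extra_sd` (see below).

## Extrapolation control

Forests do not extrapolate: predictions outside the sampled predictor
space revert to training-set means and are untrustworthy. Two surfaces
flag this:

* **strict mask** — a cell is removed when any continuous predictor is
  outside its training [min, max] or a categorical code was never seen;
* **MOP similarity** — the mean Mahalanobis distance (training-cloud
  covariance, Ledoit-Wolf shrinkage when the condition number exceeds
  1e8, e.g. from collinear one-hot columns) from the cell's predictor
  vector to the nearest 10 % of the training cloud. Mahalanobis distance
  is affine-invariant, so the raw-vs-standardised question only matters
  on the shrinkage path.

The mean and SE surfaces are published with strict-masked cells as
nodata.

## Diagnostics

* OOB residual summary: share of residuals within ±0.002 (a conventional
  reporting band for Sr isoscapes).
* Spatial correlogram: pair great-circle distances in equal-count bins, a
  Moran-style centred-product correlation per bin, and a 95 % envelope
  from permuting residuals over locations. A spline correlogram would
  answer the same question; the binned permutation version was chosen
  because its numerics are fully specified and its null is exact under
  exchangeability. Bins with < 30 pairs are flagged.
* Permutation importance on OOB data (mean OOB-MSE increase over repeats)
  and partial-dependence curves (predictor forced to v, averaged over
  training rows; out-of-range v flagged).

Collinearity screening (Pearson matrix, VIF via OLS-with-intercept,
|r| > 0.8 flagged) is advisory only; the modeller chooses the final
predictor list.

## Geographic assignment

A tissue value y becomes a per-cell likelihood
N(y | μ_c, √(σ_c² + extra_sd²)); multiplied by an optional region prior
(binary mask raster) and renormalised it is the posterior origin surface,
plus a max-normalised copy for display. Dual-isotope assignments multiply
the raw Sr and δ¹⁸O likelihoods cell-wise and normalise once; per-isotope
posteriors are retained. Enamel-carbonate δ¹⁸O (VPDB) converts to
drinking-water δ¹⁸O (VSMOW) through three affine stages
(1.03091 x + 30.91; 0.98 x − 8.5; 1.54 x − 33.72), a composition with
slope 1.5558493… and intercept −0.160628; the chain carries roughly 1 ‰
of error, added in quadrature to the water-isoscape SD (default
`o_extra_sd = 1.0` ‰). The Sr default is `sr_extra_sd = 0`; supply the
measurement error or an estimate of local natural scatter when available
(the synthetic-recovery runs use the generative within-cell sd, 0.002).

`top_fraction_region(result, q)` returns the smallest cell set holding at
least fraction q of posterior mass (ties by cell index). Note the
distinction from an *area* quantile (top q of cells ranked by
probability): for a well-calibrated posterior the q-mass region contains
the true origin with probability ≈ q, whereas area-quantile coverage is
typically much higher and is what assignment-validation studies usually
quote.

## Synthetic study conditions

The generator emulates the assumed structure of the real problem, not its
geography: Voronoi "terranes" whose per-block age sets the Sr baseline
(block means spanning 0.705–0.735, truth clipped to [0.703, 0.88]),
smooth Gaussian-field covariates (dust depressing the ratio by up to
0.008, precipitation raising it by up to 0.003, elevation inert), a
categorical lithology layer, a smooth truth-noise term (sd 0.002), and
within-cell sampling noise of sd 0.002 on observations. Standing
conditions: 200 × 200 cells (0.05°), 800 sample sites drawn uniformly
with duplicates allowed, 100 individuals, 500 trees, mtry = 2,
min_node_size = 2 (both forest hyperparameters at 2), a 20-sample
validation holdout, 5 × 10 repeated k-fold CV. What passing recovery
tests do *not* show: behaviour under the real predictors' distributions,
real spatial sampling bias, or measurement error structure of mixed
archives.

## Numerical and design choices

* "Maximum node size" is implemented as the tree grower's minimal
  terminal-node size (`min_samples_leaf`), the operative meaning of that
  tuning knob in randomForest-style toolchains.
* Neighbour infilling of missing predictor values: categorical → nearest
  valid cell, continuous → mean of the 5 nearest valid cells; distances
  between cell centres (great-circle on geographic grids, Euclidean on
  projected ones), ties broken by row-major cell index. Points on a cell
  edge belong to the cell whose west/north edge they touch.
* Raster I/O uses single-band TIFFs with the grid geometry stored as JSON
  in the image description; float payloads round-trip bit-exactly and NaN
  is the missing marker. No reprojection is attempted — stacking rasters
  on different grids is an error.
* Hyperparameter tuning refits the ensemble on every grid point and picks
  the minimal OOB RMSE, ties toward smaller mtry then smaller node size.
* All randomness flows from one root seed through named substreams
  (CRC32-keyed SeedSequence), so every artifact is bit-reproducible.

## Known limitations

* IJ standard errors estimate the sampling variance of the bagged
  predictor, not the full predictive error; they can truncate to exactly
  zero, and assignments with `extra_sd = 0` then give those cells zero
  likelihood.
* Categorical predictors are one-hot encoded; native factor splits of
  R-style forests are not replicated, so split behaviour on
  high-cardinality factors differs.
* The correlogram's equal-count bins can merge at short range when many
  pairs are co-located.
* No spatially blocked cross-validation; CV folds are random partitions,
  matching the workflow this package operationalises.
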