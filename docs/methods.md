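# Methods

`imputequal` quantifies how faithfully an imputation method reconstructs an
incomplete tabular dataset, and how imputation quality feeds through to a
downstream binary classifier. This note records the models, parameter
choices and numerical decisions behind the package.

## Problem setting

A complete dataset `D = {x_i}` of `N` samples in `R^d` (continuous,
integer-coded categorical/ordinal, and noise columns, with an optional
binary outcome) is degraded by masking cells completely at random (MCAR)
and then completed by an imputer, giving `D̂ = {x̂_i}`. Because the ground
truth is known, discrepancy between `D` and `D̂` can be measured at three
levels:

* **Class A (pointwise):** RMSE, MAE and R² of `x̂` against `x` at the
  masked cells only (observed cells are preserved bit-exactly by
  construction, so including them only dilutes the signal). By default each
  feature is divided by the standard deviation of its observed true values
  before cells are pooled, so heterogeneous units do not dominate; a flag
  disables this. R² uses the total sum of squares about the mean of the
  true masked values and is reported as undefined when they are constant.
* **Class B (feature-wise distributional):** per feature, the two-sample
  Kolmogorov–Smirnov statistic, a histogram Kullback–Leibler divergence and
  the 1-D 2-Wasserstein distance between true and imputed value
  distributions, summarised as min/median/max over features. The default
  compares values at the masked positions only (`missing_only`); the
  `full_feature` mode compares whole columns and is the variant that
  exposes marginal blindness.
* **Class C (sliced Wasserstein):** the package's centrepiece, described
  next.

## The sliced-Wasserstein discrepancy

Class A optimises pointwise recovery and class B only sees marginals: an
imputation that reflects a coordinate (truth on the diagonal `{(u, u)}`,
imputation on the anti-diagonal `{(u, -u)}` with `u` symmetric) leaves
every marginal exactly intact while destroying the joint distribution.
Random 1-D projections catch this.

Draw `M ≥ d` directions `n_r` uniformly on the unit sphere (normalised
isotropic Gaussians) and `P` random partitions of `{1..N}` into halves
`(I_p, J_p)` of sizes `⌈N/2⌉` and `⌊N/2⌋`. For each pair `(r, p)`:

* `s(r,p)` = standard deviation of `{x_i·n_r : i ∈ I_p}` (original data);
  all projections for that pair are divided by it, which makes the whole
  table invariant to a global rescaling of the data.
* `w(r,p)` = 1-D 2-Wasserstein distance between the normalised projections
  of the two *original* halves — the distance inherent to the data.
* `ŵ(r,p)` = the same with the `J_p` half taken from the imputed matrix.

The `M×P` collections `{w}` and `{ŵ}` are compared three ways:

1. as distributions, via KL/KS/W2 (a perfect imputation gives `ŵ ≡ w`
   exactly, hence zero discrepancy);
2. as per-pair ratios `ŵ/w` (mean and quantiles; ratios near 1 mean the
   imputed half sits within the data's own split-to-split variability);
3. as outlier proportions `P(ŵ > threshold)`. The threshold has **no
   default**: its scale depends on the dataset and normalisation, so it is
   a deliberate user parameter.

Pairs with `s < 1e-12` are skipped and listed rather than scored. Defaults:
`P = 10`; `M = 2d` (presets `M = 50` and `M = 90` are exported for
moderate-width numeric and wider mixed datasets respectively). The baseline
comparison uses the two flattened `M×P` samples, not per-`J_p` pairing.

Repeating the table over the `m` completions of a multiple imputation with
the *same* directions and partitions splits the spread of `ŵ` into a
within-table part (random projections) and a between-table part (imputer
stochasticity); a deterministic imputer has exactly zero between-table
variance.

### 1-D statistics

* **KS:** ECDFs (right-continuous) compared at the union of sample points,
  where every jump occurs; exact.
* **2-Wasserstein:** equal sizes reduce to the RMS difference of sorted
  samples; unequal sizes integrate the squared quantile-function difference
  exactly on the `1/lcm(n_a, n_b)` grid (integer index arithmetic, no
  floating-point breakpoints). Verified in tests against a
  discrete-transport linear program.
* **KL:** shared equal-width histogram over the pooled range (default 30
  bins) with `ε = 1e-10` additive smoothing then renormalisation. A
  histogram estimator was chosen over density-based variants for
  determinism and an exact small-case oracle; KL values therefore depend on
  the bin count and are comparable only at a fixed setting.

## Synthetic data generator

`generate_numeric(n, d, class_sep, seed)` draws each class from a
unit-variance isotropic Gaussian centred at a vertex of the hypercube
`{-class_sep, +class_sep}^d`, with the two classes at *opposite* vertices
so that every feature carries class signal (`class_sep` is half the
per-coordinate vertex gap). Labels are balanced to within one sample and
everything is bit-reproducible from the seed. Default study conditions are
1000 samples × 25 informative features at `class_sep = 1.0`.

`generate_mixed` appends integer-coded categorical (3 levels) and ordinal
(4 levels) columns obtained by quantile-binning additional latent
informative Gaussian draws — the codes stay predictive of the outcome —
plus standard-normal uninformative columns independent of the labels. The
level counts are configurable; the discretisation by quantiles is the
package's choice, made for reproducibility and preserved informativeness.

What the generator does **not** emulate: feature correlations within a
class (features are conditionally independent given the label), label
noise, multi-cluster classes, redundant features, MAR/MNAR mechanisms, and
the heavy tails/mixed missingness of real clinical tables. Passing tests on
this generator therefore demonstrates correctness of the measures and the
qualitative orderings between imputers, not performance claims on clinical
data. One consequence worth stating plainly: at the default conditions the
two classes are far apart (centroid distance `2·class_sep·√d ≈ 10`), so the
downstream classification task is close to saturation and holdout AUC
differences across missingness rates are small; the degradation with test
missingness shows as a weak ordering (and clearly in the Brier score),
while the distributional damage of poor imputation is large and obvious in
the class C scores.

## Missingness, splits, imputers

* **MCAR:** the default `exact_count` policy masks exactly
  `round(rate·N·d)` cells uniformly without replacement, making the nominal
  25%/50% rates exactly checkable; a `bernoulli` policy (independent
  per-cell) is available. Labels are never masked. An optional guard
  redraws masks that empty a whole row/column; it is **off** by default
  because pure MCAR carries no such protection.
* **Splits:** the default plan draws 3 independent development/holdout
  repeats (holdout fraction 0.25, a configurable choice) and partitions
  each development set into 5 cross-validation folds whose sizes differ by
  at most one.
* **Mean imputation:** observed column mean (continuous) or mode (coded;
  ties to the smallest level). Deterministic, single completion.
* **Chained equations (MICE family):** initialise missing cells by
  mean/mode; for `n_iter` sweeps visit columns left-to-right (fixed order
  for reproducibility) and redraw each column's missing entries from a
  regression on all other columns — ordinary least squares plus a Gaussian
  residual draw (σ from the observed-row residuals) for continuous columns,
  a logistic fit plus a Bernoulli draw for binary-coded columns; other
  coded columns use the linear draw projected to the nearest declared
  level. Degenerate designs (constant predictors or response) fall back to
  a mean/mode draw with a warning rather than failing. `m` independent
  chains give `m` completions. Defaults `m = 5`, `n_iter = 10` (common
  practice); the qualitative benchmark runs use `m = 1`, `n_iter = 5`, which
  is already well past convergence at these problem sizes.
* **External imputers** (e.g. forest- or neural-network-based) plug in via
  `register_external_imputation`, which validates that observed cells are
  untouched and no sentinels remain. Imputed coded values are expected as
  level codes; the nearest-level/argmax post-processing convention is the
  package's documented choice for methods that return values in between.

## Downstream harness

`run_scenario` masks the development and holdout sets at their own rates,
imputes each, selects the hyperparameter grid point with the best mean
validation AUC over the 5 folds × `m` completions (ties go to the first
declared point), refits on the full development set per completion, scores
the holdout per completion and pools — probability averaging by default,
majority vote (ties to the positive class) as the alternative. Reference
classifiers: a regularised logistic fit and a random-forest ensemble; any
object with `fit`/`predict_proba` plugs in through `ClassifierSpec`. AUC is
the Mann–Whitney statistic (ties count ½); the other metrics are standard
confusion-matrix quantities at threshold 0.5 plus the Brier score.
`skewness` (biased moment form `m₃/m₂^{3/2}`) summarises the symmetry of
externally supplied feature-importance value vectors;
`correlate_quality_vs_performance` returns the Pearson correlation and
least-squares slope, with grouping by test rate left to the caller because
the rate drives both quantities.

## Numerical and design notes

* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng` / `SeedSequence`); identical calls are
  bit-identical, and CSV round-trips use 17-significant-digit formatting
  with round-trip float parsing.
* Zero-width pooled range in KL (both samples one constant) returns 0;
  differing constants necessarily widen the range.
* `stability_analysis` reports exactly 0 between-table variance when all
  per-table means coincide, avoiding spurious `1e-34`-scale float residue.
* The outlier-proportion boundary `threshold = 0` is allowed and returns
  the fraction of strictly positive `ŵ`.
* Problem sizes in the shipped tests and the reproduction script (≤ 20
  seeds × 1000×25 tables at `M = 50`, `P = 10`; LP oracles on ≤ 6-point
  samples) are the package's desk-scale defaults, chosen so a full run
  completes in minutes on one core.

## Known limitations

* The chained-equations imputer is a reference implementation (linear /
  logistic conditionals only), not a full MICE engine: no predictive-mean
  matching, no multi-level categorical logistic draws, no convergence
  diagnostics.
* KL estimates are histogram-based and bin-sensitive; treat them as
  comparable scores, not divergence estimates.
* The class C score requires all features numeric-coded; one-hot/ordinal
  codes participate in projections as real values.
* MAR/MNAR mechanisms are out of scope; real-data missingness enters only
  pre-baked in user CSVs, where ground truth — and hence classes A–C — is
  unavailable and only the downstream harness applies.
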