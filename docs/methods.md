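# Methods

## The measure and its estimation

For a dataset `s` of `n` i.i.d. observations with a binary outcome, let
`e_full,K(s)` and `e_incompl,K(s)` be the misclassification rates from full
and incomplete K-fold CV (definitions in the README). The package estimates

```
CVIIM(s, n, K) = max(0, 1 − e_incompl,K(s) / e_full,K(s))   (0 if e_full,K(s) = 0)
```

with both errors averaged over `B` repeated CV runs. The ratio form makes
the measure comparable across datasets with different error levels; the
additive alternative `max(0, e_full − e_incompl)` is provided only for
comparison, since its size tracks the error itself. The measure is a
plug-in estimate of a population quantity (expectations over samples of
size `n`); no variance estimate is attempted — the variance of a ratio of
two correlated CV errors is notoriously hard to estimate — and the
per-repetition INIMEs with their 25%/75% quartiles (type-7 linear
interpolation) are reported instead as a relative variability cue. The mean
of the INIMEs is *not* the CVIIM value (mean of ratios ≠ ratio of means);
they agree only when every repetition produces identical errors.

The *global* CVIIM replaces each error with its average over a collection
of datasets before forming the ratio. This damps the influence of datasets
whose tiny full-CV error would otherwise produce extreme individual
values. `run_study` warns (without failing) below 10 datasets, where a
collection-level statement rests on a thin universe.

### Pairing and seed discipline

Repetition `b` of the full and the incomplete scheme share a fold
partition; partition seeds derive from `(master seed, K, b)` only, never
from the scheme. INIMEs therefore reflect incompleteness, not partition
noise, and an empty step chain yields `e_full = e_incompl` *exactly* and
CVIIM = 0 on any dataset (the null-calibration test). Whether repeated CV
should instead re-randomize partitions independently per scheme is a
defensible alternative; it only adds partition noise to the difference and
leaves the B-run means asymptotically unchanged, so pairing was chosen.
All remaining randomness (internal tuning folds, stochastic plug-in
classifiers) flows from the same master seed through a fixed
`SeedSequence` counter scheme; identical inputs reproduce results bitwise.

### Folds, pooling, degenerate cases

Folds are stratified by class: the intended datasets are small, and
stratification keeps every training fold two-class, which every classifier
here requires. A class smaller than K is an explicit infeasible-partition
error; a training fold that still loses a class is a hard error, never a
silent skip. Within a run the error is pooled over all n observations
(equivalently fold-size weighted); per-repetition INIMEs with zero full-CV
error are dropped (not zeroed — zeroing would bias the quartiles) and the
drop count is surfaced.

### Rules of thumb

CVIIM values are labeled on left-open/right-closed bins:
[0, 0.02] no influence, (0.02, 0.1] weak, (0.1, 0.2] medium,
(0.2, 0.4] strong, (0.4, 1] very strong. These are interpretive
conventions, not tests.

## Preparation steps (addon contract)

Every step separates into `fit` (estimate parameters on training data) and
the fitted state's `transform` (apply those frozen parameters to any
matrix, down to a single row — the one-patient-at-a-time case is the reason
addon procedures exist). Transforming the training data through the addon
path *is* its fit-time preparation; there is no second code path.
Unsupervised steps expose `fit(X)` only, so the interface itself guarantees
they cannot read labels.

* **Quantile normalization** stores the mean of the sorted training rows as
  the reference; any observation's sorted values are replaced by the
  reference, reassigned by its own ranks. Tied raw values receive the mean
  of the reference values at the tied ranks (the tie rule is otherwise
  undefined; this keeps the output sort-order independent).
* **Global VSN** applies `arsinh((x − a)/b)`, a glog that behaves like a
  log at high intensity. Only the two dataset-level parameters are
  estimated — offset `a` = the 5% quantile of training intensities, scale
  `b` = 1.4826·MAD of the below-25%-quantile stratum — a deliberately
  simple robust scheme isolated behind the step interface so a different
  estimator can be swapped in; the contract (global parameters, addon
  reuse on test data) is what matters for incompleteness.
* **PCA** stores training column means and the leading right-singular
  vectors of the centered training matrix; the addon centers by the
  *training* means and projects. Each loading column's largest-magnitude
  entry is made positive (SVD signs are arbitrary; tests need determinism).
* **t-test selection** ranks variables by pooled-variance two-sample
  t-test p-values (Welch optional); zero-variance variables get p = 1;
  ties break to the lower column index. The addon selects exactly the
  training-chosen columns.
* **Variance filtering** keeps the m largest-training-variance variables
  (ties to the lower index).
* **Mean imputation** stores training column means and fills missing
  entries in training and test from them; an all-missing training variable
  is a fit failure. This is a representative simple imputer, not a claim
  that mean imputation is the method of choice.
* **Tuning** is a supervised chain step: internal 3-fold stratified CV over
  the classifier's grid, smallest error wins, ties break toward the
  simpler model (largest NSC shrinkage, smallest PLS component count or RF
  mtry). Before the incompleteness boundary it reproduces tuning once on
  the whole dataset; after it, the parameter is re-chosen per training set.

## Classifiers

NSC follows the classical shrunken-centroid construction
(soft-thresholded standardized centroid deviations with the median-`s_j`
offset and `m_k = sqrt(1/n_k − 1/n)`). LDA uses the pooled within-class
covariance, requires `n > p + 1` and raises on singularity with a hint to
reduce dimension first — it is meant to run after selection or PCA. DLDA
is LDA with a diagonal pooled covariance (defined for `p >> n`); variances
are floored at `1e-12` times their mean to stay defined on constant
columns. PLS-LDA extracts NIPALS components against the centered binary
response (scikit-learn's `PLSRegression`, no scaling; SIMPLS would differ
only in later components and is not offered) and runs LDA on the scores.
Priors are empirical by default, configurable to uniform. Random forest is
not reimplemented; it participates through the plug-in registry as a
seeded wrapper around scikit-learn's implementation.

## Synthetic data

The generator draws Gaussian predictors with a block-equicorrelated
covariance (blocks of `block_size` at correlation `rho`, independent
across blocks) — a self-contained parametric stand-in for the gene-cluster
correlation of transcriptomic data; the qualitative conclusions checked
here (leakage ordering, sample-size dependence) do not hinge on the exact
covariance. The first `n_informative` variables get a class-mean shift of
`effect_size` marginal SDs. Defaults — 40 observations, 2000 predictors,
blocks of 25 at rho = 0.4, 20 informative variables at a one-SD effect —
emulate the small-n/large-p two-class microarray regime. Options: an
intensity-scale version (per-variable lognormal baselines in [20, 2000]
with multiplicative noise, so the SD grows with the mean — the regime a
glog stabilizes) and a missing-completely-at-random mask. Missingness is
MCAR only; informative missingness, batch structure, heavy tails and
array-level artifacts of real data are *not* emulated, so passing tests
demonstrate correct mechanics and direction of effects, not real-data
magnitudes.

## Problem sizes in the end-to-end checks

The replicated null-data studies run at a desk scale chosen once:
20 replicate datasets, n = 40, p = 2000, B = 50, K = 5 for the leakage
ordering (supervised selection vs variance filtering vs quantile
normalization), and 10 replicate datasets per sample size with B = 25 for
the n = 30 vs n = 120 comparison. The miniature study presets default to
B = 25 with K ∈ {3, 5, 10} and document the classical grids (psel ∈
{5, 10, 20, p/2}; PCA components {2, 5, 10, 15}; NSC shrinkage
{0.05, 0.1, 0.25, 0.5, 1, 1.5}; PLS components 1–10; RF mtry
{1, 2, 3, 5, 10}); B = 300 remains the default of `StudyConfig` for real
studies.

## Known limitations

Binary misclassification loss only (the measure generalizes to any
positive-range loss; not implemented). No confidence intervals for CVIIM.
CV is dataset-internal validation: CVIIM says nothing about external
validation, where preparing external data separately can even be
preferable. Per-dataset CVIIM values on datasets with very small full-CV
errors are unstable; prefer the global estimate and the K-sensitivity
analysis (`sensitivity_drop_datasets`, which drops the datasets with the
largest `|e_full,K1 − e_full,K2|`).
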