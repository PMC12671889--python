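# Methods

## Regularized CCA

For standardized training matrices X (n × p) and Y (n × q) the solver
computes sample covariances with denominator n − 1 (correlation
matrices, given standardization), shrinks the within-set covariances as
R_x = (1 − c_x) C_xx + c_x I (likewise R_y), and takes the singular
value decomposition of the whitened cross-covariance

    W_x C_xy W_y,   W = R^(−1/2).

Weights are u = W_x U_k, v = W_y V_k, normalized so u′ R_x u = 1.
Inverse square roots use symmetric eigendecomposition with an
eigenvalue floor of 1e-12 — at p ≈ 148, q ≈ 68 the primal formulation
is cheap and no dual/kernel trick is needed. At c → 0 this reproduces
classical CCA (checked against an independent generalized-
eigendecomposition oracle to 1e-6); at c = 1 it reduces to the singular
vectors of C_xy (the PLS limit, checked to 1e-8). Components are
ordered by nonincreasing training canonical correlation. Scores are
plain projections Xu, Yv; canonical correlations are Pearson
correlations of score pairs; loadings are variable–score correlations.
The sign of each (u_k, v_k) pair is indeterminate and every downstream
comparison is invariant to joint flips.

Shared regularization c_x = c_y is the default (a single
hyperparameter); separate values are accepted by the solver.

## Multiple-holdout framework

* Outer level: 5 independent random 80/20 optimization/holdout splits
  (repetitions, not folds). Optional stratification keeps label
  proportions within ±1 subject per partition (largest-remainder
  allocation per stratum).
* Inner level: 5 independent 80/20 train/test splits of each
  optimization set.
* Selection: per candidate c, fit on each inner training set
  (preprocessing refitted on those rows), record the inner-test
  canonical correlation of the first component and the weight
  stability (mean |pairwise Pearson r| of first-component weights
  across inner splits, averaged over the u and v sides). Candidates are
  ranked on mean test correlation and on stability, both descending;
  the minimal rank sum wins and ties go to the more regularized
  candidate, favoring stability. The default grid is
  {0, 0.1, 0.3, 0.5, 0.7, 0.9, 0.99, 1 − 1e-4}.
* Evaluation: refit on the full optimization set with the selected c,
  project the holdout; the observed statistic is the signed first
  holdout canonical correlation (the training-set first correlation is
  nonnegative by construction and the holdout statistic inherits that
  orientation). Each of n_perm = 1,000 permutations shuffles the rows
  of Y independently within the optimization and holdout sets and
  refits with the same c. Because row shuffling leaves C_xx, C_yy and
  all row-wise preprocessing unchanged, the refit reuses the whitening
  transforms and recomputes only C_xy — algebraically identical to a
  full refit. raw p = (1 + #{null ≥ observed}) / n_perm, so the floor
  is 1/n_perm and the Bonferroni-corrected floor is 5/n_perm = 0.005 at
  the defaults. A refit failure inside a permutation is counted as
  null ≥ observed (conservative).
* Omnibus rule: the dimension is significant iff at least one of the
  five corrected p-values is below alpha (0.05).
* Deflation: projection deflation — every column of X is residualized
  on the removed x-score and every column of Y on the removed y-score.
  Slopes and score means are estimated on the optimization rows of each
  split and applied to its holdout rows, keeping deflation
  cross-validation-consistent. (The deflation formula is not uniquely
  pinned down by the framework's verbal description; projection
  deflation is the recorded assumption, as it literally removes the
  dimension's variance from the data and is well defined
  out-of-sample.)
* Loading aggregation: loadings are computed on the optimization set of
  each outer split (the largest sample available to each model; this
  choice is recorded in the run manifest). Splits 2–5 are sign-aligned
  to split 1 by the Pearson correlation of risk-factor loading vectors
  (the same flip applies to both sides; an alignment correlation within
  ±0.1 of zero triggers a warning). Reported per variable: mean, sample
  SD (ddof = 1, the plotted error bar), and the stability flag
  |mean| > SD. The worked reference case {0.5, 0.5, 0.5, 0.5, −0.1}
  gives mean 0.38, SD 0.268, stable — which pins the SD convention to
  the sample SD.

Preprocessing nesting: confound regression (OLS on an intercept +
numeric confounds + k−1 dummies per categorical, first level dropped)
and standardization are fitted on the optimization rows of each outer
split and applied to its holdout; hyperparameter selection refits
standardization (and confound regression, when confounds are passed
explicitly) within every inner training set. For dimensions ≥ 2 the
deflated matrices are already confound-free, so the inner loop
re-standardizes only. Confounds are removed from both X and Y; in the
mixed-sex sample the confound set is {age, sex, site}, in sex-stratified
runs {age, site}. The composition order is fixed: brain-size scaling →
confound removal → standardization. Brain-size scaling offers raw,
proportional (subject-wise division by the global reference, e.g.,
mean cortical thickness or total intracranial volume), and corrected
(residualization on the global reference with training-estimated
coefficients).

## Spin-permutation nulls

Parcel centroids live on the unit sphere, split equally across
mirrored hemispheres. Each spin draws a Haar-uniform rotation
(QR of a Gaussian matrix with sign correction, determinant +1), applies
it to left-hemisphere centroids and the x-mirrored rotation to the
right, and reassigns each parcel the value of its nearest original
same-hemisphere centroid (Euclidean metric, duplicates permitted —
simpler than unique matching and unbiased for correlation statistics;
recorded in output metadata). Permutation 0 is reserved as the
identity for self-tests and excluded from the null count. The test is
two-sided on |correlation| (both positive and negative associations are
of interest), with raw p = (1 + #{|null| ≥ |observed|}) / (n_perm + 1),
guaranteeing p > 0. Annotation batteries use Spearman correlation and
Bonferroni correction at the battery size; hemisphere-incomplete maps
are rejected with an error rather than special-cased. Risk-factor
loading profiles across models are compared with signed Pearson
correlation and its analytic p-value.

## Subject scores and external associations

Every subject is projected through each outer split's model after
re-applying that split's training-estimated preprocessing; the
per-split scores are sign-aligned with the same flips as the loadings
and averaged (holdout-only scores can be assembled from the per-split
score lists for leakage-sensitive uses). Associations with external
variables use Spearman rank correlation (midranks for ties, analytic
large-sample p) with Bonferroni correction at a caller-declared family
size, since the relevant battery size depends on how many markers and
dimensions a study examines. Because the orientation of a canonical
dimension is arbitrary, the sign of a reported association is
meaningful only relative to the loading orientation of the same run;
the magnitude is the stable quantity.

## Synthetic cohort generator

The generator emulates the statistical structure the pipeline assumes,
not the marginal distributions of any real cohort.

* Geometry: left-hemisphere centroids on a Fibonacci lattice covering a
  half-sphere, right hemisphere mirrored through x = 0 — guaranteeing
  the mirror symmetry the spin null assumes; real centroid tables can
  replace them via `geometry.csv`.
* Planted dimensions: for each dimension k a standard-normal brain-side
  factor t_k enters X through a spatially smooth weight map (white
  noise smoothed with the kernel exp(−d²/2σ²) on chord distance, the
  simplest stationary autocorrelation on the sphere; maps of successive
  dimensions are orthogonalized) and the risk-factor-side factor enters
  Y through per-block signed magnitudes (default 3.0 on one block per
  dimension, zero elsewhere — with constant within-block weights the
  planted direction is an exact eigendirection of the noise, keeping
  the population canonical direction equal to the injection direction).
  The latent pair correlation is raised to r/(α_x·α_y), where the α are
  closed-form attenuation factors from the isotropic measurement noise
  (default SD 1.0), so the population canonical correlation of the
  observed matrices equals the configured r; targets that become ≥ 1
  after noise raise a configuration error. The recorded ground truth
  (weights, latent score pairs, configured correlations) supports
  parameter-recovery tests.
* Risk-factor blocks: each block shares a latent noise factor giving
  within-block correlation ρ (default 0.6), emulating the
  body-composition and air-pollution clusters of population panels.
* Confounds: age uniform on [46, 81] (the emulated cohort's age range),
  sex balanced, site 4-level uniform; effects enter linearly on the
  standardized confound (defaults 0.2/0.1/0.05 on X and 0.1/0.1/0.05
  on Y for age/sex/site).
* Marker: exp of a Gaussian linear predictor whose correlation with the
  chosen dimension's risk-factor-side factor is set by inverting the
  bivariate-normal Spearman relation ρ_S = (6/π)·asin(ρ/2) — CRP-like
  right skew with a tractable rank link (default target −0.39).
* Study-scale defaults: n = 7,370 subjects, 68 risk factors, 148
  parcels, two planted dimensions at canonical correlations 0.32 and
  0.10 (the middle of the ranges reported for the cardiometabolic and
  physical-robustness dimensions in the emulated study).

What the generator does **not** emulate: real marginal distributions of
risk-factor fields (only the correlation-block topology and scale),
non-linear confound effects, heteroscedastic or spatially correlated
measurement noise in the brain block, missing data (incomplete records
are rejected, not imputed), and site-specific covariance differences.
Passing recovery tests therefore show the machinery is correct and
calibrated under its own assumptions, not that any particular real
cohort satisfies them.

## Numerical choices and degenerate inputs

* Eigenvalue floor 1e-12 in matrix inverse square roots; covariance
  denominator n − 1.
* "Uncorrelated after residualization" tolerance: 1e-10 on training
  rows (exact arithmetic up to floating point).
* Rank deficiency of confound designs is detected on unit-normalized
  columns (scale-invariant) and reported with the offending column
  names; unseen categorical levels at transform time are an error, not
  an extrapolation.
* Zero-variance columns: an error in standardization (named), NaN with
  a flag in loadings and correlation matrices.
* Selection ties break toward the larger regularization; rank ties use
  minimum ranks.
* p-value conventions: (1 + exceedances)/n_perm for the framework
  permutation test (floor 1/n_perm, reproducing the printed corrected
  floor of 0.005 exactly at the defaults) and
  (1 + exceedances)/(n_perm + 1) for spin tests.
* All randomness flows from a single seed through spawned seed
  sequences; every consumed seed is logged in the run manifest, and
  identical configurations reproduce outputs bit-for-bit.

## Problem sizes used by the test suite

The statistical guarantees are exercised at desk scale: the permutation
floor on an n = 500 cohort (p = 40, q = 20, planted r = 0.6, 1,000
permutations); two-dimension sequential recovery at the study's matrix
sizes (n = 4,000, p = 148, q = 68, 200 permutations); type-I error over
200 null cohorts (n = 400, reduced grid, 200 permutations); spin
calibration with 500 spins over 200 repetitions on the 148-parcel
geometry. The recovery band (±0.07) is asserted on the mean holdout
correlation across the five outer splits per dimension: with an 800-row
holdout the per-split correlation carries sampling error ~0.033, so the
mean is the quantity that estimates the planted value at that
tolerance.

## Known limitations

* The permutation scheme shuffles preprocessed Y rows; exchangeability
  is assumed after confound removal.
* Loadings are computed on optimization rows; holdout-only loadings are
  not currently produced.
* Nested-CV unbiasedness beyond what the multiple-holdout scheme itself
  provides is not claimed; outer splits share subjects, so the five
  holdout correlations are positively dependent (the Bonferroni-omnibus
  rule remains valid, just conservative).
* The spin null conditions on the chosen parcellation geometry;
  vertex-level nulls and variogram/generative spatial nulls are out of
  scope.
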