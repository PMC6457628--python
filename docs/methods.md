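# Methods

`plsdecode` implements a two-step decoding pipeline for block-design fMRI:
feature selection by (sparse) partial least squares regression or a
voxel-wise GLM, followed by a PLS regression classifier with an argmax
readout, plus the simulator and evaluation harness needed to study the
pipeline under controlled contrast-to-noise ratios (CNR).

## The PLS core

Given a centered data matrix `X` (n volumes × p voxels) and a centered
dummy-coded label matrix `Y` (n × q tasks), components are extracted
sequentially.  At stage k the residuals are the projections onto the
orthogonal complement of the accumulated score matrix `T`:

    X_k = (I − P_T) X,   Y_k = (I − P_T) Y,   P_T = T T⁺

and the direction vector `r_k` maximizes `rᵀ Z_kᵀ Z_k r` subject to
`‖r‖ = 1`, with `Z_k = Y_kᵀ X_k`.  We compute `r_k` as the dominant right
singular vector of `Z_k` through the q × q Gram matrix `Z_k Z_kᵀ` — the
deterministic fixed point of the classical NIPALS power iteration, with no
convergence-tolerance ambiguity.  Sign convention: the largest-magnitude
entry of `r_k` is positive.  Because scores are mutually orthogonal under
projection deflation, `P_T` is applied incrementally as a rank-1 update.

After K stages the direction matrix that maps centered data straight to
scores is assembled as

    W = R (Gᵀ R)⁻¹,   G = Xᵀ T (Tᵀ T)⁻¹,   R = (r_1 … r_K),

so `T = X_c W`, the response loadings are `Q_Y = Yᵀ T (TᵀT)⁻¹`, and the
coefficient matrix is `B = W Q_Yᵀ`.  Predictions are
`(X_new − x̄) B + ȳ`; the centering offsets are stored in the model and
applied at test time.  Both X and Y are deflated; deflating only X gives the
same fitted values (the direction at each stage is unchanged because the
score space is shared), so the choice is not observable in predictions.

Properties maintained (and tested): score orthogonality to 1e-8, unit-norm
raw directions to 1e-10, `T = X_c W` to 1e-8, and equality with the
normal-equation OLS solution when K = rank(X) and n > p.  If the
cross-covariance vanishes before K components are extracted, the model keeps
the components found and warns instead of failing, so heavily penalized
sparse fits degrade gracefully.

One caveat worth recording: a single PLS component reproduces a noiseless
rank-1 signal `Y = X b cᵀ` exactly only when `b` is invariant under `XᵀX`
(e.g. orthonormal predictor columns); for general X the first direction is
proportional to `XᵀX b`, and exact recovery needs K = rank(X).  The tests
exercise both regimes.

## Sparse directions

The sparse variant replaces the dense direction with the coordinate-wise
penalized least-squares problem

    min_r  Σ_j [ ½‖Z_j − C r_j‖² + λ|r_j| ],   C = Y_resid ᵀ t,

whose closed-form solution is `r_j = soft(CᵀZ_j, λ)/(CᵀC)` with
`soft(a, λ) = sign(a)·max(|a|−λ, 0)`.  Because the score `t` itself depends
on `r`, the direction is a fixed point; we iterate the closed form starting
from the unpenalized direction (everything runs on the q × p matrix
`Z = Y_residᵀX_resid`, since `C = Z r`).  At λ = 0 the starting point is the
fixed point, so the sparse model reduces exactly (to 1e-8) to the dense one.
Zeros are exact, never small floats; the thresholded direction is rescaled
to unit norm for consistency with the dense constraint.  One λ is shared
across components (a per-component λ would make the CV grid K-dimensional
for no observed benefit at these problem sizes).

λ is tuned by stratified cross-validated MSE of the predicted indicator
matrix over a 21-point grid: {0} plus a geometric ladder up to just below
the first-stage `max_j |CᵀZ_j|` (the smallest λ that empties the
direction).  Ties prefer the larger λ (the sparser model).  Grid points that
empty the first direction on some fold score infinity; if every point does,
tuning fails loudly.

## Feature selection and the classifier

For selection, a PLS (or sparse PLS) model of the dummy-coded task labels is
fitted on all voxels of the training run; each column of the coefficient
matrix `B` (p × q) is converted to z scores (sample sd, n−1 — configurable),
and voxels with z strictly greater than 3.5 are kept for that task.  The
final mask is the union over tasks, with per-task provenance retained.  The
GLM baseline fits each voxel's time course on the HRF-convolved task
regressors plus an intercept by OLS and keeps voxels whose one-sided t-test
p is below 0.001 (uncorrected), per task, union over tasks.

The number of latent components K is chosen by stratified 5-fold CV
(grid 1..min(10, n−1, p), MSE of the predicted indicator against the 0/1
labels, ties toward smaller K).  The loss uses the raw indicator rather than
the centered one; the two rankings are identical because the centering
offset is carried by the model.

The classifier refits a PLS regression on the masked training columns; a
test volume gets the class with the largest predicted response score.  Exact
argmax ties go to the smallest task index and are counted and warned about.
Test volumes are masked with the training-run mask; selectors and
classifiers never see test-run values (the evaluation tests poison the test
run with sentinels and verify the trained model is bit-identical).

Normalization follows a fixed order: each voxel's time course is
standardized to zero mean / unit variance, then each volume's spatial
pattern is standardized across voxels.  Zero-variance voxels are excluded
(zeroed, indices recorded) before the second pass so train/test indexing
stays aligned; a zero-variance volume is an error.

## The simulator

Each run is 16 task blocks of 12 s (4 blocks per task, order randomized per
run) alternating with 17 rest blocks of 6 s, TR 2 s → 147 volumes, of which
96 are task volumes (24 per task).  Images are 270 × 270 pixels (default) at
baseline 800.  The HRF is the canonical double-gamma (response gamma shape
6/scale 1 s, undershoot shape 16/scale 1 s weighted 1/6, length 32 s),
sampled at TR and peak-normalized to 1; regressors are boxcars convolved
with this kernel and truncated to the run.  Task signal
`amplitude × regressor` is added inside that task's ROI; the shared ROI
receives the sum of all four regressors.  Noise is Rician:
`out = sqrt((v+n₁)² + n₂²)`, `n₁,n₂ ~ N(0, σ²)`.

Parameters that matter:

- **CNR** ∈ {0.05, 0.1, 0.2, 0.4} by default.  Realized as
  `amplitude = CNR·σ` with σ = 30 image units.  Only the ratio is
  observable after the pipeline's standardization, so σ's absolute value is
  a free scale.  Note the regressor plateau is the kernel *sum* (≈ 2.6 at
  TR 2) rather than 1, since the kernel is peak-normalized; the effective
  per-volume contrast is therefore ≈ 2.6·CNR·σ during sustained blocks.
- **ROI layout**: the published figure's exact geometry is not recoverable,
  so the default layout is parametric — four square task ROIs centered in
  the quadrants and a shared square at the center, side = 7% of the grid
  (361 pixels each at 270², 49 at 96²), pairwise disjoint.  Ground truth is
  stored with the study and used for recovery scoring.
- **Label timing**: a volume is labeled by the block covering
  `onset − shift` with `shift = 4 s` by default (configurable, including 0).
  The BOLD response to a block arrives ~5 s late — the convolved regressor
  is ≈ 0 during the first two volumes of every block — so onset labeling
  would assign half of each block's volumes the wrong generating signal.
  The 4-s shift keeps the block bookkeeping intact (still 96 task volumes,
  24 per task).  Rest volumes are never classification samples: with rest
  excluded, the rows of the centered indicator sum to zero, so the PLS fit
  sees only between-task contrasts.  This is precisely why PLS selection
  ignores the shared ROI (task-vs-rest signal, no between-task contrast)
  while the GLM — fitted on the full run against per-task regressors —
  flags it.
- **Motion** (off by default): per-volume random-walk 2-D translation with
  bilinear resampling; a noise condition, not part of the tested defaults.

Per-run generators derive from
`SeedSequence(master, spawn_key=(cnr_index, subject, run))`, so a master
seed reproduces any run bit-identically without storing the study.

What the simulator does *not* emulate: 3-D geometry and rotation,
physiological noise and temporal autocorrelation, spatial smoothness of
real BOLD fields, between-subject anatomical variability, and
region-specific response amplitudes.  Passing recovery and trend tests
therefore demonstrates internal consistency of the method under the stated
generative model, not performance on real fMRI.

## Evaluation harness

Six methods = {sparse-PLS, PLS, GLM} selectors × {PLS argmax, one-vs-one
linear-SVM voting} classifiers, named SP_PLSR, P_PLSR, G_PLSR, SP_SVM,
P_SVM, G_SVM.  Per subject, run 1 trains the selector and classifier and
run 2 is scored; selector masks are fitted once per subject and shared by
the two classifiers that use them.  The SVM comparator trains all q(q−1)/2
binary linear SVMs (regularization C chosen by stratified CV per pair) and
aggregates by majority vote; vote ties go to the smallest task index.  A
subject whose selector returns no features is recorded as a failed cell,
not a crash.

Group-level voxel patterns: one-sample t across subjects per voxel,
one-sided p < 0.001, then 8-neighbour connected components strictly larger
than 25 voxels survive (a 25-voxel cluster is removed).  Method comparisons
use two-sided Wilcoxon signed-rank tests on paired per-subject accuracies
(zeros dropped), α = 0.05.

## Problem sizes used in tests and the acceptance script

The factorial experiment runs at 15 subjects × 4 CNR levels × 6 methods on
a 96 × 96 grid — the full subject and CNR design with the image plane
scaled down, preserving ROI proportions (side = 7% of the grid either way).
The trend assertions compare means with a one-pooled-standard-error slack:
monotonicity in CNR and the SP_PLSR ≥ G_SVM ordering are asserted per CNR
level; the classifier ordering (PLS ≥ voting at fixed selector) and the
selector ordering (PLS/sparse-PLS ≥ GLM at fixed classifier) are asserted
on means pooled across CNR levels, since per-level differences at
near-chance CNRs are dominated by noise.  Numerical oracles (OLS limit,
soft-threshold scan, λ=0 reduction) and null-calibration rates run at the
sizes stated in their tests.
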