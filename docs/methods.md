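# Methods

This note documents the models, conventions and numerical choices behind
`icalearn`, in the spirit of the methods documentation of packages like
statsmodels or msprime: what is computed, under which assumptions, with
which defaults, and what the synthetic experiments do and do not show.

## Data model and group ICA

A subject scan is a T × V matrix (time points by in-mask voxels) on a
`VolumeGrid`; real data enter through 4-D NIfTI plus an optional binary
mask, with 0-based voxel indexing and affines carried through untouched.
No resampling or registration is performed: multi-site data must already
share a grid.

Group ICA follows the temporal-concatenation convention of the GIFT
family of tools:

1. per-subject PCA to `n_sub_pc` temporal modes (default **40**). Data
   are mean-centered per voxel over time; no variance normalization. The
   temporal modes are eigenvectors of the T × T covariance; because
   centering removes one mode, `n_pc = T` is accepted as the identity
   case while `n_pc` beyond the centered rank is a degenerate-input
   error.
2. stacking the reduced subject matrices and a second PCA to `K`
   (default **30**) group modes.
3. Infomax ICA on the whitened group modes. The implementation uses
   runica-style stochastic block updates of the natural-gradient rule
   W ← W + η (block·I + (1 − 2g(u))uᵀ) W with the logistic nonlinearity
   g, block size ⌊√(V/3)⌋, learning rate η = 1e-3 annealed by 0.98
   whenever the update direction turns by more than 60°, restart with
   halved η on weight blow-up, and stopping when the squared per-pass
   weight change falls below 1e-6 (`max_iter` 1000 passes; hitting it is
   a recorded warning state, not an exception). The logistic
   nonlinearity assumes super-Gaussian sources, which the synthetic
   generator's Laplace time courses satisfy.

ICA sign and scale ambiguity is removed deterministically: each spatial
map is scaled to unit variance and its sign set so that spatial skewness
is non-negative; PCA eigenvector signs are fixed by making the
largest-magnitude entry positive. With these conventions the
decomposition is a pure function of (data, seed): scaling all scans by a
positive constant or reordering subjects leaves the maps unchanged (the
latter up to component order, recovered by matching).

## Dual regression

Subject-specific maps come from two least-squares stages, both with an
intercept: time courses from regressing each time point's voxel pattern
on the group maps, then maps from regressing each voxel's time series on
the **variance-normalized** time courses. Normalizing the time courses
puts the component's temporal standard deviation into the subject map
amplitude, which is the quantity the group comparison then
discriminates on. Rank-deficient or zero-variance group maps raise a
`SingularDesignError` naming the offending components.

## Template matching

A `ComponentTemplate` holds the selected reference maps (default 16 of
30 in the full-scale configuration). Matching computes the full Pearson
correlation table over in-mask voxels and then repeatedly takes the
globally largest |corr| among unmatched template rows and candidate
columns — the sequential greedy rule — recording the correlation's sign
so candidates can be sign-aligned. Ties break to the lower template,
then lower candidate index, making the output unique. A globally
optimal Hungarian assignment is available for diagnostics only. Manual
visual screening of components is replaced by a user-supplied list of
selected indices plus an automated screening report (spatial skewness,
kurtosis, suprathreshold fraction) and a matched-|corr| warning
threshold (default 0.4).

## Per-component classifiers and voting

For each matched component, with training maps X (N × V) and labels:

- **t map**: pooled-variance two-sample t per voxel, SZ minus HC;
  zero-variance voxels get t = 0 and a flag. Both classes need ≥ 2
  members.
- **Threshold t₀**: candidates are the 50th–99th percentiles of |t|
  (two-sided by default; a signed variant is available). For each
  feasible candidate (≥ d + 1 surviving voxels) the full
  threshold → kernel PCA → FLD chain is fit and the Fisher ratio
  J = (m₁ − m₂)²/(s₁² + s₂²) of the 1-D training projections recorded;
  the argmax wins, ties to the smaller t₀. J, not inner CV accuracy, is
  the criterion because it is deterministic and measures exactly the
  class separation the final discriminant produces on training data.
- **Kernel PCA**: double-centered kernel eigendecomposition with the
  out-of-sample rule k_c(x) = k(x,·) − row/column/total means. Default
  kernel is Gaussian with bandwidth = median pairwise training distance
  (γ = 1/(2h²)); linear is available. Default retained dimension
  d = 10, clipped to N − 1; d beyond the centered kernel's rank is an
  error. Implemented directly in numpy (the matrices are ~30 × 30;
  sklearn's KernelPCA serves as a cross-check in the test suite).
- **FLD**: w = (Σ_w + λI)⁻¹(μ_SZ − μ_HC) with λ = 1e-6 × mean diagonal
  of Σ_w; threshold at the midpoint of projected class means; score =
  x·w − threshold; SZ iff score > 0, exact zero → HC. All-identical
  projections yield a flagged chance-level classifier with a warning.
- **Voting**: majority label across components; on a tie the sum of
  scores, each divided by its component's training-score SD, decides
  (positive → SZ, exact zero → HC).

Sensitivity refers to SZ, specificity to HC, and
accuracy = (sens·N_SZ + spec·N_HC)/(N_SZ + N_HC) holds exactly in every
report.

## Validation settings

- **Internal (LOO)**: for each held-out subject, group ICA, template
  matching, dual regression of training subjects, t maps, t₀, kernel
  PCA and FLD are all recomputed from the remaining subjects only; the
  held-out subject contributes data solely to its own dual regression
  and prediction, and its label to nothing. This is deliberately
  expensive — the decomposition is refit per split — because reusing a
  full-set decomposition would leak the held-out subject's data into
  feature extraction.
- **Direct external**: template and every classifier parameter come from
  the training site; test scans are dual regressed on the training-site
  template maps and scored frozen.
- **Transfer external**: joint group ICA over training scans plus
  *unlabeled* copies of the test scans (labels are stripped before any
  fitting step, so passing labels into the training path is impossible
  by construction), greedy matching to the training-site template, then
  supervised refit on training labels only.
- **Permutation test**: the supplied procedure is rerun with uniformly
  permuted training labels; p = (1 + #{null ≥ observed})/(1 + n_perm).
  Default n_perm = 2000 for full-scale runs; tests use 49. For external
  settings the model is refit per permutation and scored on the true
  test labels.

An `ensemble_digest` (SHA-256 over every trained array) supports exact
no-leakage audits: flipping all held-out or test labels must leave the
digest bit-identical.

## Synthetic cohorts

The generator emulates exactly the generative model group ICA assumes:
scan = gain · (TC · diag(loadings) · M_site) + ε, with

- M: K_true unit-norm spatial maps, each a sum of 1–3 Gaussian bumps at
  random in-mask centers (σ ∈ [1, 2.5] voxels), resampled until all
  pairwise |corr| < 0.3 (a configuration error if the grid cannot hold
  that many decorrelated blobs);
- TC: i.i.d. unit-variance Laplace time courses (super-Gaussian, the
  regime Infomax assumes);
- loadings: 1 + N(0, 0.1²) per subject and component; for SZ subjects
  the loadings of the affected components are multiplied by
  (1 + effect_size) — diagnosis expresses as stronger expression of
  specific networks;
- site effects: multiplicative gain, site-specific Gaussian noise SD,
  and an integer-voxel periodic displacement of the maps — the minimal
  triad that reproduces the qualitative failure of direct between-site
  generalization;
- scan lengths default to 195 and 175 retained volumes for the two
  sites (200/180 acquired minus five dummy volumes) and default cell
  sizes mirror the two cohorts (51/51 and 27/34); tests use reduced
  sizes.

A fixed seed makes cohorts byte-identical (`numpy` `SeedSequence`
spawning per subject). The returned `TruthRecord` exists for test
oracles only; no pipeline stage reads it. The generator deliberately
omits hemodynamics, physiological noise spectra and head motion —
preprocessing is outside the package's scope — so passing tests show
correctness of the decomposition/classification machinery under the
ICA generative model, not robustness to real-scanner artifacts.

## Problem sizes in tests and the acceptance script

End-to-end experiments run on reduced grids chosen once as the smallest
sizes at which each phenomenon is stably measurable: 8×8×4 grids
(12×12×8 for ICA recovery), K_true = 4–6 components, 8–15 subjects per
group, 36–60 time points, subject PCA to 10–20 modes. The acceptance
script uses 12 repetitions for averaged quantities and 100 for the
permutation-calibration KS; the test suite uses 50 and 200.

Two behaviors of the full procedure at these scales are worth knowing:

- **Null LOO accuracy sits slightly below 0.5** (≈ 0.43–0.47 at 15+15
  subjects). Leave-one-out with training-set-tuned feature selection is
  pessimistically biased on null data — removing a subject shifts its
  class mean away from it, and majority voting over correlated
  component votes compounds the per-component bias. The bias shrinks
  with sample size; it is a property of the procedure, not a defect of
  the implementation.
- **Permutation p-values on null data are mildly conservative** because
  accuracies are discrete and ties inflate the add-one count; the
  calibration experiment therefore uses 24 held-out subjects so the
  accuracy grid is fine enough for the KS statistic to be meaningful.

## Known limitations

- Infomax is the non-extended variant; sub-Gaussian sources are out of
  scope (the generator never produces them).
- No ICASSO-style stability resampling and no estimation of the model
  order K.
- The component count and kernel/dimension defaults (16 components,
  RBF, d = 10) are configuration, not estimated quantities.
- Headline accuracies from the motivating study (0.725 within-site,
  0.550 direct external, 0.700 transfer external) were computed on
  undeposited patient data; the package reproduces the qualitative
  pattern on synthetic cohorts but makes no claim about those exact
  numbers.
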