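# Methods

## Model

Each data view (a tabular block of continuous measurements, or a
channel-first 2D/3D image) is modelled by its own invertible flow to a
Gaussian base, giving exact per-sample log-likelihoods by the
change-of-variables formula.  Views of one subject are assumed matched
(same subject, pre-aligned images); the model performs no resampling or
registration.

**Tabular flows.**  K affine coupling layers with alternating even/odd
feature masks (an odd dimension puts the extra feature in the first
partition).  Each conditioner is a two-hidden-layer tanh MLP of width HC
whose final layer is zero-initialized, so the flow starts at the identity.
The predicted log-scale is squashed as `s = c·tanh(raw/c)` with cap
`c = 3` by default; `c = 0` degenerates couplings to pure shifts.  Defaults
K = 4, HC = 80 — the configuration selected for imaging-derived-phenotype
views by validation likelihood, small enough not to overfit cohorts of a
few hundred subjects.  Bases: a trainable diagonal Gaussian, or a
Gaussian-PCA base fitted post hoc on collected latents whose rank-r
whitened coordinates give views with different widths a matched alignment
dimensionality (truncation affects only the alignment head, never
invertibility).

**Preprocessing** is dataset-owned and invertible: mean imputation of
missing entries (before marginal transforms, so transforms always see
complete data), an optional monotone per-feature transform (log, log1p,
asinh, or rank-Gaussianization using Hazen plotting positions (k−0.5)/n to
avoid infinite quantiles), then standardization or min-max rescaling with
the per-column scale floor-clamped (default 1e-6) so constant columns stay
finite.

**Image flows.**  Per level: squeeze (channel-major rearrangement of each
2^S block; 3D squeeze multiplies channels by 8), K steps of ActNorm →
invertible 1×1(×1) convolution → affine coupling, then a split that sends
the *first* half of the channels to the latent; the last level exits
fully.  ActNorm is initialized from a warm-up batch (≥ 8 samples; sd floor
1e-6 for degenerate channels) and its statistics are fixed thereafter.
The 1×1 convolutions are LU-parameterized with a fixed permutation and
fixed diagonal signs, so `log|det W| = (∏N_i)·Σ log|diag U|` is read off
the parameters.  Coupling conditioners are two-hidden-layer ReLU
convolutions with 3^S kernels and a zero-initialized last layer.  The base
over each latent block is a channel-wise diagonal Gaussian — one mean and
one log-scale per channel broadcast over space (2C parameters regardless
of resolution), log-scales clamped to |s| ≤ 5.  Per-level step counts may
be a list, indexed shallow → deep.

**Alignment.**  The latent of each view is split into shared and private
blocks; a per-view MLP projector (hidden H = 512, output D = 256 by
default) maps the shared block to a common embedding space.  Five
objectives are implemented, all returned so that lower is better and all
pairwise losses averaged over unordered view pairs (this keeps the meaning
of the weight λ stable as views are added): Pearson (negated mean
correlation of batch-normalized embeddings), Barlow Twins
(cross-correlation to identity; off-diagonal weight 5e-3), VICReg
(invariance/variance/covariance = 25/25/1, hinge 1.0), InfoNCE (cosine
similarity, in-batch negatives, temperature 0.1), and biased HSIC with RBF
kernels (bandwidth: median heuristic on the batch).  Batch normalization
is applied inside the correlation-based losses only (Pearson, Barlow);
VICReg/InfoNCE/HSIC see raw embeddings.  A shrinkage of 1e-4 enters the
variance denominators.  λ = 0 skips the alignment term entirely, so the
objective equals the pure likelihood sum bit-for-bit.

**Screening** selects the shared subspace on projector outputs after a
likelihood-only warm-up (defaults: warm-up 1000 iterations, refresh every
5000, retained fraction 0.5, ridge 1e-3).  CCA mode whitens each view with
a ridge-regularized covariance, takes the SVD of each pairwise
cross-covariance, averages per-view directions over pairs and
re-orthonormalizes by QR (so projector columns are orthonormal, which the
plain average does not guarantee).  HSIC mode prefilters coordinates by
maximum absolute Pearson correlation with any other view, ranks survivors
by mean unbiased HSIC against the other views' retained blocks, and keeps
the top r with ties broken toward lower indices.  Screening never touches
flow parameters.

**Optimization.**  Adamax with learning-rate warm-up then
reduce-on-plateau; global-norm gradient clipping (default 0.2; the tiny
image smoke runs use a looser 5.0 since their likelihood scale is large);
EMA of parameters (decay 0.999) maintained for sampling/inference while
alignment always sees live parameters.  Gradient accumulation: likelihood
gradients are summed over A microbatches and normalized by the total
sample count — exactly equal to the non-accumulated gradient at λ = 0 —
while alignment is computed within each microbatch and divided by A, so
its covariance/negative statistics are local to the microbatch (a
documented approximation).  Additive dequantization jitter follows named
decay schedules (`name:kind:v0->v1` with kinds linear, cos, exp; values
clamp to v1 after the horizon); Gaussian jitter for tabular data, uniform
for images.  Train/validation splits are made at the subject level from
the run seed.

## Conditional Gaussian over latents

With flows frozen, per-subject latents are concatenated (levels within
view, views sorted by name).  Each (view, level) block is divided by its
scalar standard deviation before fitting so no single high-variance view
dominates the eigen-spectrum; the scalars are stored and undone on decode.
The Gaussian uses μ = sample mean, U/Λ = top-r SVD of the centered data
(Λ the raw top-r eigenvalues), and σ² = mean residual variance over the
discarded directions, floored at 1e-8; optional shrinkage blends Λ toward
its mean.  Default rank r = min(n−1, 64, D−1).

Conditioning on observed coordinates O uses the push-through Woodbury
identity: with `B = U_O Λ^{1/2}` and `K = BᵀB + σ²I_r`,

```
μ_{U|O}    = μ_U + U_U Λ^{1/2} K⁻¹ Λ^{1/2} U_Oᵀ (z_O − μ_O)
Σ_{U|O}    = σ² (I + U_U Λ^{1/2} K⁻¹ Λ^{1/2} U_Uᵀ)  =  F Fᵀ + σ² I,
F          = σ · U_U Λ^{1/2} L⁻ᵀ,   K = L Lᵀ .
```

Only the r×r K is Cholesky-factorized (adaptive jitter starting at
1e-10·trace/r, ×10 per retry, 3 retries); Σ_OO is never formed, and the
conditional covariance stays in factored low-rank-plus-diagonal form so
sampling costs O(|U|·r).  Log-densities and Mahalanobis distances use the
matrix-determinant lemma and the same solves; a guard refuses to
materialize any dense D×D object above D = 4096.  Imputation encodes the
observed views, conditions, rescales by the stored block scalars, and
decodes the conditional mean through each target view's inverse flow;
any observed subset may predict any disjoint target subset.

## Latent geometry

In dimension d, standard-normal mass concentrates on a shell of radius
≈ √d (Gaussian annulus); the origin is a high-density but
measure-negligible point.  Operations: Slerp (with cosine clamped to
±(1−1e-7) before arccos; collinear endpoints fall back to linear
interpolation and antipodal endpoints are rejected as ambiguous),
mean-centered Slerp `μ + slerp(z1−μ, z2−μ, t)` which preserves the radius
of equal-radius endpoints, angular geodesic distance, standardized
Euclidean (diagonal Mahalanobis) distance `√Σ(z_i−μ_i)²/(σ_i²+ε)`,
temperature sampling (base scaled by τ; latent norms concentrate at
τ√d), and the template `f⁻¹(0)` — a barycentric anchor of the bijection,
not a typical sample.  Multiscale latents are flattened and concatenated
in level order before any geometry operation.

## Synthetic data

The generators define the study conditions for every test.  Tabular:
n = 500 subjects, a 2-D shared factor and 2-D per-view private factors,
8-feature views, linear (or smooth monotone, `x + 0.5·tanh x`) mixing,
noise sd 0.1 — small enough that shared structure is recoverable, large
enough that recovery is non-trivial.  Imaging: 16×16 (or 8³) phantoms with
a smooth-edged ellipse whose center and radii vary per subject, identical
geometry across a subject's views, and per-view monotone gamma-style
intensity transfers — emulating co-registered multimodal MRI where anatomy
is shared and contrast is view-specific.  Augmentation mirrors the
training stack: shared small affine and Gaussian-smoothed random
deformations (smoothing sd 4 voxels) driven by a geometric seed common to
a subject's views, then per-view mean-one exponential-polynomial bias
fields, monotone piecewise-cubic histogram warps, and additive noise.
What the phantoms do **not** emulate: anatomical detail, lesions,
registration error, scanner noise structure; passing tests show the
machinery is correct and recoverable at desk scale, not that the model
captures real anatomy.

## Numerical and design choices

* Everything runs in float64 on a small in-package reverse-mode autodiff
  engine over numpy; convolutions are im2col matmuls.  This trades speed
  for exactness and zero framework dependencies; the test and acceptance
  workloads use desk-scale problems (2-D tabular flows trained 2000 steps,
  a 1×16×16 L=2 K=4 HC=32 image flow trained 2000 steps at batch 8, 500–
  1000-subject synthetic cohorts), which run in minutes on one CPU.
* BPD uses the continuous convention, −log₂ p(x)/d with no dequantization
  offset: inputs are continuous measurements, and the quantity can
  legitimately be negative for low-variance data.
* The spec of equal treatment between once-after-warm-up and periodically
  refreshed screening is resolved by supporting both through
  `screen_warmup_iters` / `screen_refresh_iters`.
* Degenerate inputs: constant columns are floor-clamped; constant ActNorm
  channels get an sd floor; zero-variance Gaussian fits floor σ² at 1e-8
  with a logged warning; HSIC of a constant view is exactly zero.
* Ties in HSIC screening break toward lower coordinate indices; QR signs
  in CCA screening are fixed by making each R diagonal positive, so
  screening is deterministic given its inputs.

## Limitations

* The engine is single-device and unvectorized across coupling layers;
  training realistic-resolution 3D models is out of reach here (the
  architecture builds and round-trips at the published configurations, but
  training at those sizes is not attempted).
* Masked autoregressive conditioners, variational dequantization,
  attention couplings, and mixed precision are out of scope.
* The Gaussian-PCA base is fitted, not trained end-to-end by gradient.
* Imputation returns the conditional mean (plus samples on request); no
  uncertainty maps beyond conditional draws.
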