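# mvflow

Multiview normalizing flows with latent alignment, closed-form cross-view
imputation, and latent-space geometry, aimed at multimodal biological
imaging: subject-matched tables of imaging-derived phenotypes (IDPs) and
pre-aligned 2D/3D image volumes.

## The problem and the model

Multimodal studies observe each subject through several *views* — e.g. a
T1-weighted MRI, a FLAIR image, a table of IDPs.  `mvflow` equips every
view *v* with its own invertible flow `f_θ^(v)` mapping observations to a
Gaussian latent space with an exact log-likelihood via the
change-of-variables formula

```
log p(x) = log p_Z(f(x)) + log |det ∂f/∂x| .
```

Tabular views use single-scale affine-coupling flows (RealNVP family) with
alternating even/odd masks, MLP conditioners, and bounded coupling scales;
image views use multiscale Glow flows (squeeze → ActNorm → invertible
1×1(×1) convolution with LU parameterization → convolutional affine
coupling → split) with a channel-wise diagonal Gaussian base (2C parameters
regardless of resolution).

Flows are trained jointly on subject-matched minibatches.  Each latent is
split into shared and private blocks, `z = [z_S, z_P]`, and a per-view MLP
projector maps `z_S` into a matched D-dimensional embedding on which an
alignment loss acts:

```
L(θ, ψ) = (1/N) Σ_n Σ_v −log p_θ(x_n^(v))  +  λ · L_align({φ_ψ^(v)(z_S,n^(v))})
```

with `L_align` one of Pearson correlation, Barlow Twins, VICReg, InfoNCE,
or HSIC (pairwise losses averaged over unordered view pairs; λ = 0 recovers
pure maximum likelihood bit-for-bit).  The shared subspace can be chosen by
CCA or HSIC *screening* after a likelihood-only warm-up.

After training, the concatenated per-subject latents (all levels of all
views) are modelled as `z ~ N(μ, UΛUᵀ + σ²I)`.  A 64³ volume already has
D ≈ 2.6·10⁵ latent coordinates — a dense covariance would exceed 500 GB —
so all conditioning goes through the push-through Woodbury identity: only
the r×r matrix `K = Λ^{1/2} U_Oᵀ U_O Λ^{1/2} + σ²I` is factorized.
Cross-view imputation encodes the observed views, computes the exact
conditional mean of the missing views' latents, and decodes it through the
target views' inverse flows.

Latent navigation respects high-dimensional Gaussian concentration:
spherical linear interpolation (optionally centered on the population mean)
instead of straight lines, angular geodesic and (standardized) Mahalanobis
distances, temperature-scaled sampling, and the latent-origin template
`x = f⁻¹(0)`.

## Worked example

`examples/03_cross_view_imputation.py` builds two smoothly coupled tabular
views, trains one flow per view, fits the latent Gaussian, and imputes the
held-out view for 500 test subjects:

```
feature 0: imputed-vs-true correlation = 0.989
feature 1: imputed-vs-true correlation = 0.984
feature 2: imputed-vs-true correlation = 0.995
feature 3: imputed-vs-true correlation = 0.987
feature 4: imputed-vs-true correlation = 0.993
feature 5: imputed-vs-true correlation = 0.994
```

Correlations near 1 mean the conditional mean carries subject-specific
signal across views rather than collapsing to the population average.  The
other examples cover density estimation (`01`, BPD within ~0.01 bits of the
analytic entropy of a correlated Gaussian), the effect of alignment (`02`,
embedding correlation 0.10 → 0.97 when λ goes from 0 to 0.01), image-flow
training and templates (`04`), and latent geometry (`05`, lerp midpoint
norm 0.72 vs slerp 1.00 in d = 512).

A thin CLI mirrors the tool workflow: `mvflow train`, `sample`,
`gauss-fit`, `gauss-impute` (alias `impute`), `recon-template`,
`recon-temperature`, `recon-interpolate`, `calc-distance`.

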