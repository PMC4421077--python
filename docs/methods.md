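# Methods

This note documents the models implemented in vesselkit, the parameter
choices that matter, the numerical decisions taken where the design was
open, and what the synthetic phantoms do and do not establish about real
fundus images.

## Image model and conventions

All stages operate on 2D float64 arrays indexed `[row, col]`; nominal
8-bit intensities in [0, 255] are assumed by the default PSNR peak
(d = 255) and by the 8-bit writers, but nothing else depends on the
range. Vessels are modelled as *dark* tubes with a Gaussian
cross-section I(d) = background − contrast·exp(−d²/2r²) on a brighter
background; the tube "radius" r is the Gaussian scale of that profile,
and the detector identifies radius with detection scale (σ = r). Bright
structures are handled by inverting the image, not by duplicating the
eigenvalue logic. Vector fields (eigenvectors, diffusion bases) store
(row, col) components; eigenvector signs are fixed by requiring a
nonnegative first nonzero component, with exact ties resolved to the
coordinate axes, so all outputs are deterministic and regression-testable.

## Diffusion denoising

**Perona–Malik.** Explicit flux-form scheme: per axis, half-pixel fluxes
F = g(|Δu|)·Δu on forward differences, update u += dt·(F⁺ − F⁻).
Replicated (Neumann) borders give zero boundary flux, so total intensity
is conserved to machine precision and, for dt ≤ 0.25 (the enforced 2D
stability bound; out-of-range dt raises rather than clamps), the update
is a convex combination of neighbors — the discrete maximum principle
holds. With g ≡ 1 the scheme is exactly the 5-point explicit heat
equation, which the tests exploit as an oracle. Both printed diffusivity
variants are available; k sets the gradient magnitude treated as "edge".

**Directional anisotropic diffusion.** Each iteration recomputes, from
the *current* iterate, the basis v₁ ∥ ∇u_σ (σ = `sigma_reg`, default
0.8 px), v₂ ⊥ v₁, and projects the raw central-difference gradient on it
to get u_{v₁}, u_{v₂}. The flux φ₁(u_{v₁})v₁ + φ₂(u_{v₂})v₂ with
φ₁(s) = s·e^{−(s/k)²}, φ₂(s) = α·s is assembled and its divergence taken
by central differences (the vector flux has no natural half-pixel
decomposition, unlike the scalar PM case). The attachment term is
implemented as +β(u₀ − u), attraction *toward* the original: the
alternative sign printed in some statements of the model makes u₀ a
repeller and diverges. Flat regions (|∇u_σ| < 1e−8) fall back to the
Hessian eigenvectors of the smoothed image, then to the coordinate axes;
in all fallback branches the directional derivatives vanish, so constant
images are exact fixed points. α is accepted on (0, 1]: α < 1 gives the
intended anisotropy, α = 1 with φ₁ = identity and β = 0 degenerates to
the (central-difference) heat equation, which is tested. The
central-difference divergence is not monotone; on extremely rough input
with β = 0 and many iterations the iterate can leave the input range.
The attachment term (default β = 0.05) and moderate iteration counts
(defaults follow the published benchmark rows, e.g. N = 50, k = 7,
dt = 0.05, σ = 0.8 for the vessel test image) keep it well-behaved in
practice.

## Scale-space analysis

Gaussian (derivative) kernels are truncated at radius ⌈4σ⌉ with
replicated borders; scale-normalized derivatives multiply by σ^order.
The per-pixel 2×2 symmetric Hessian eigen-decomposition is closed-form,
choosing per pixel the better-conditioned eigenvector branch; ordering
is λ₁ ≥ λ₂ always. Degeneracy (λ₁ ≈ λ₂, relative discriminant ≤ 1e−9)
uses the fixed-axis convention. Trace, determinant and the reconstruction
H = Σλᵢeᵢeᵢᵀ are preserved to 1e−6 RMS (tested).

Candidate preselection operationalizes the ideal dark-tube signature
(λ₂ ≈ 0 < λ₁) with two knobs: |λ₂| ≤ ratio·λ₁ (default ratio 0.5) and λ₁
at or above the `strength_quantile` quantile (default 0.25) of the
positive-λ₁ population, restricted to interior pixels. The rule is a
recall-oriented heuristic: on a bright-on-dark tube it correctly rejects
every axis pixel, but the convex shoulders of the inverted profile can
still qualify — eigenvalue signs alone cannot distinguish a dark ridge
from the flanks of a bright one. Gating the response by preselection is
off by default (the offset-gradient response itself recovers pixels the
eigenvalue analysis misses, e.g. vessels with a bright central reflex);
it is available as a flag for speed or strictness.

## Medialness response and scale normalization

The single-scale response samples the first-derivative-of-Gaussian
gradient at the two offset points M ± σd (d = e₁) by bilinear
interpolation and combines the two signed, dark-tube-oriented dot
products, clamping negatives to zero. Signed-then-clamp is the default
because it suppresses bright-line false positives; an absolute-value
variant is exposed (`use_abs`) for polarity-agnostic detection. Offset
points falling outside the image yield response 0.

Scale weighting enters exactly once, as the σ^γ factor applied by
`normalize_response`: the sampled gradient is *not* pre-multiplied by σ,
so γ = 1 reproduces the standard first-order scale normalization
(multiply first derivatives by σ) and is neutral — a tube of radius r
probed at σ = r and its magnified copy at σ = 2r score equally (tested
to 10%, empirically ≲0.1%). Applying the σ factor in both places would
weight the multiscale maximum by σ^{1+γ}, which demonstrably breaks both
scale invariance and radius recovery (the maximum migrates to the
largest scale on every tube); with the single factor, the winning scale
on bars of radius 4 and 2.2 under the {1.25, 2.22, 3.94, 7} grid is the
grid point nearest the true radius, as the acceptance tests check.
γ > 1 biases the maximum toward thick vessels, γ < 1 toward thin ones
(tested as a direction on a two-bar phantom).

The multiscale map is the pointwise maximum of the normalized per-scale
maps (verified exactly against a brute-force stack), rescaled to [0, 1]
by the global maximum — a simple choice made explicit here because any
monotone rescale leaves ROC/AUC untouched; identically zero maps stay
zero. `argmax_sigma` records the winning scale per pixel.

## Evaluation

The ROC sweep uses `n_thresholds` (default 256) evenly spaced thresholds
in [0, 1] with the tie rule response ≥ T → vessel, rather than the exact
response quantiles: cost is bounded and the curve is dense enough that
AUC differs from the exact rank statistic by < 1e−3 in the tested
regimes. Endpoints (0,0) and (1,1) are appended before trapezoidal
integration so constant responses score 0.5. Pixels outside a supplied
FOV mask are excluded from all four confusion counts (counting them as
true negatives would inflate accuracy and deflate FPR). MAA is the
maximum of the accuracy curve, reported with its threshold and operating
point; accuracy is computed inside the FOV. PSNR uses peak 255 and
returns +inf at zero MSE. The FOV construction thresholds the gray
image, keeps the largest connected component and fills holes.

## Phantoms: what they establish and what they do not

The generator produces straight bars (any orientation, sub-pixel axis
placement) and rings with Gaussian cross-sections, optional 8-bit
quantization, and seeded additive i.i.d. Gaussian noise (default test
level: σ = 20 intensity units on ~100-contrast tubes, a clearly visible
but not overwhelming corruption; noise is never clipped implicitly,
since clipping biases PSNR). These phantoms exercise the geometry the
detector reasons about — profile shape, curvature, radius variation,
polarity — so the passing tests establish correctness of the response
model, scale selection, combiner behavior and the evaluation arithmetic.

They deliberately do not emulate fundus backgrounds: no illumination
gradients, optic disk, lesions, central vessel reflex, branching, or
spatially correlated acquisition noise. Two consequences observed in the
acceptance runs are worth recording. First, against i.i.d. Gaussian
noise the detector's own per-scale Gaussian derivatives are already an
effective matched filter, so a DAD pre-denoising pass raises image PSNR
(≈ +1.2 dB at the benchmark parameters) but leaves phantom segmentation
MAA essentially unchanged (±0.003 across noise levels 20–60); the
segmentation benefit of diffusion pre-filtering reported on real retinal
data rests on structured background variation that these phantoms lack.
Second, absolute AUC/MAA values on phantoms (≈ 0.99+) are far above
anything achievable on real fundus images and should be read only as
ordering/sanity checks, never as performance claims.

## Problem sizes and determinism

Tests and the acceptance script run on 65–128 px phantoms, 4-scale
grids, and ≤ 256² noise fields — sizes at which every property being
asserted is already stable, as the scale-invariance and oracle tests
confirm. All stochastic inputs flow from explicit integer seeds
(`NoiseSpec.seed`, the acceptance script's `--seed`); phantom generation
and the full pipeline are otherwise deterministic, and identical
config + seed reproduces output files bit-exactly.
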