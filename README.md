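# vesselkit

Multiscale medialness detection of 2D curvilinear structures, with
edge-preserving anisotropic-diffusion denoising and a full ROC evaluation
stack. The package targets the classic retinal-image problem — extracting
the blood-vessel tree from a fundus photograph, where vessels appear as
dark, roughly Gaussian-profile tubes of widely varying width on a brighter
background (highest contrast in the green channel) — but every stage works
on any grayscale image containing dark tubular structures, and a phantom
generator makes the whole pipeline testable without any dataset.

## Method

**Denoising.** Perona–Malik diffusion ∂u/∂t = div(g(|∇u|)∇u) with
g(s) = 1/(1+(s/k)²) or exp(−(s/k)²), in a conservative flux-form explicit
scheme, and *directional anisotropic diffusion* (DAD): the flux is
decomposed in the orthonormal basis (v₁ ∥ ∇u_σ, v₂ ⊥ ∇u_σ) of the
σ-regularized image, with diffusivities φ₁(u_{v₁}) = u_{v₁}e^{−(u_{v₁}/k)²}
across the structure and φ₂(u_{v₂}) = α·u_{v₂} (0 < α ≤ 1) along it, plus
a data-attachment term β(u₀ − u):

∂u/∂t = Σᵢ div(φᵢ(u_{vᵢ}) vᵢ) + β(u₀ − u).

This smooths along vessels while leaving their edges intact. Gaussian and
median filters are included as baselines.

**Detection.** At scale σ, with d = e₁ the unit eigenvector of the larger
eigenvalue λ₁ of the smoothed Hessian H_σ (λ₁ ≥ λ₂; for a dark tube
λ₂ ≈ 0 < λ₁ and e₁ crosses the tube), the medialness response at pixel M
combines the two offset directional derivatives

R_σ(M) = combine( ∇I_σ(M + σd)·d , ∇I_σ(M − σd)·(−d) ),  combine ∈ {max, mean, min},

sampled by bilinear interpolation, clamped at zero. Responses are
normalized by σ^γ (γ = 1 is the neutral, scale-invariant choice) and
maximized over a logarithmic scale grid between the smallest and largest
vessel radius (radius = scale), e.g. {1.25, 2.22, 3.94, 7} for radii
1.25–7 at 4 scales:

R*(x) = max_{σ∈Σ} σ^γ R_σ(x),

rescaled to [0, 1], with the winning scale per pixel estimating the local
vessel radius. Hessian-eigenvalue preselection (λ₁ > 0, |λ₂| ≤ ratio·λ₁,
strength quantile) can optionally gate the computation.

**Evaluation.** MSE and PSNR = 10·log₁₀(255²/MSE) for denoising;
threshold-sweep ROC (prediction = response ≥ T, T on an even grid in
[0, 1]) restricted to an optional field-of-view mask, with trapezoidal
AUC and the maximum accuracy (MAA) operating point.

## Worked example

```python
from collections import Counter
import vesselkit as vk

scales = vk.log_scales(1.25, 7.0, 4)           # [1.25, 2.22, 3.94, 7.0]
spec = vk.VesselPhantomSpec(radius=4.0)        # dark tube, radius 4 px
img = vk.make_bar_phantom(spec, 65, 65)
res = vk.multiscale_response(img, scales, gamma=1.0, combiner="max")

axis = vk.bar_axis_mask(spec, 65, 65)
print(res.response[axis].mean())               # 0.907  (strong on-axis response)
print(Counter(res.argmax_sigma[axis]).most_common(1))
# [(3.94, 65)] -> every axis pixel is detected at the scale nearest the
# true radius 4; the winning scale doubles as a radius estimate
```

Running `python examples/04_evaluation_roc.py` on a 100×100 8-bit ring
phantom (a maximally curved vessel) prints

```
combiner      AUC      MAA  recall@MAA
max        0.9999   0.9960      1.0000
mean       0.9990   0.9900      0.9206
min        0.9989   0.9900      0.9206
```

i.e. only the max combiner recovers the full ring at the maximum-accuracy
threshold — on a curved tube the two offset points see different edge
geometry, and max is robust to that asymmetry. The other `examples/`
scripts demonstrate phantoms and noise (01), the denoisers and edge
preservation (02), detection and radius recovery (03) and the end-to-end
configured pipeline (05); each prints the numbers it computes and what
they mean.

## Command line

```bash
vesselkit synth ring.png --shape ring --size 100 --radius 2 --noise-sigma 20 --seed 1
vesselkit denoise ring.png den.png --method dad --k 1.25 --beta 0.05 --iters 30
vesselkit detect den.png resp.png --rmin 1.25 --rmax 7 --scales 4 --gamma 1 --combiner max
vesselkit evaluate --pred resp.png --truth gt.png --fov fov.png
vesselkit pipeline --config run.cfg
```

Exit codes: 0 success, 2 bad parameters, 3 I/O failure.

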