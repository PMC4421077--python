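"""Multiscale medialness response — the core vessel detector.

At a scale sigma, a pixel M close to the axis of a dark tube of radius
~ sigma has two boundary points M1 = M + sigma*d and M2 = M - sigma*d on
either side, where d is the unit cross-section direction (the Hessian
eigenvector of the larger eigenvalue).  The gradient of the smoothed image
at M1 points outward along +d and at M2 along -d, so the two signed
directional derivatives

    t1 = grad_sigma I(M1) . (+d),    t2 = grad_sigma I(M2) . (-d)

are both positive exactly when M sits between two edges a tube-diameter
apart.  The single-scale response combines t1 and t2 (max, mean or min),
clamping negatives to zero; gradients at the off-grid points are sampled
by bilinear interpolation.

Responses are made comparable across scales by the normalization factor
sigma^gamma: gamma = 1 reproduces the first-order scale normalization of
scale-space theory (multiplying first derivatives by sigma) and is neutral
in the sense that no scale is preferred; gamma > 1 favors large scales,
gamma < 1 small ones.  The multiscale map is the pointwise maximum of the
normalized single-scale responses over a geometric (logarithmic) scale
grid between the smallest and largest vessel radius of interest, rescaled
to [0, 1], with the winning scale recorded per pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import ndimage

from ._validation import GrayImage, as_image
from .scalespace import CandidateSet, HessianField, hessian_eigen, gaussian_derivative, preselect_candidates

__all__ = [
    "ScaleSpec",
    "ResponseMap",
    "MultiscaleResult",
    "log_scales",
    "single_scale_response",
    "normalize_response",
    "multiscale_response",
]

_COMBINERS = ("max", "mean", "min")


@dataclass(frozen=True)
class ScaleSpec:
    """Geometric scale grid from ``r_min`` to ``r_max`` (vessel radii in
    pixels, radius == detection scale) with ``n_scales`` entries; the
    logarithmic spacing gives more resolution at small scales."""

    r_min: float
    r_max: float
    n_scales: int
    sigmas: np.ndarray


def log_scales(r_min: float, r_max: float, n_scales: int) -> ScaleSpec:
    """Build the logarithmically discretized scale set.

    Endpoints are included; consecutive ratios are equal.  The standard
    retinal setting ``log_scales(1.25, 7, 4)`` yields
    {1.25, 2.22, 3.94, 7}.
    """
    if not 0 < r_min <= r_max:
        raise ValueError("need 0 < r_min <= r_max")
    if n_scales < 1:
        raise ValueError("n_scales must be >= 1")
    if n_scales == 1:
        if not np.isclose(r_min, r_max):
            raise ValueError("n_scales == 1 requires r_min == r_max")
        sigmas = np.array([float(r_min)])
    else:
        sigmas = np.geomspace(r_min, r_max, n_scales)
    return ScaleSpec(float(r_min), float(r_max), int(n_scales), sigmas)


@dataclass(frozen=True)
class ResponseMap:
    """Single-scale medialness response: nonnegative ``values`` at scale
    ``sigma`` with the endpoint ``combiner`` used; ``normalized`` records
    whether the sigma^gamma factor has been applied."""

    values: np.ndarray
    sigma: float
    combiner: str
    normalized: bool = False


@dataclass(frozen=True)
class MultiscaleResult:
    """Final detector output: ``response`` in [0, 1], per-pixel
    ``argmax_sigma`` (the winning scale), the ``gamma`` used, the scale
    grid and combiner for provenance."""

    response: np.ndarray
    argmax_sigma: np.ndarray
    gamma: float
    sigmas: np.ndarray
    combiner: str


def single_scale_response(
    image: GrayImage,
    sigma: float,
    combiner: str = "max",
    direction_field: Optional[HessianField] = None,
    gate: Optional[CandidateSet] = None,
    use_abs: bool = False,
) -> ResponseMap:
    """Offset-gradient medialness response at one scale.

    ``direction_field`` must be a Hessian field computed at the same
    ``sigma`` (it is computed on the fly when omitted); d = e1, the
    cross-section direction.  Signed dot products oriented for dark tubes
    are combined and clamped at zero; ``use_abs`` switches to the
    absolute-value reading (which also responds to bright lines).  Pixels
    with either offset point outside the image get response 0, as do
    pixels outside the ``gate`` candidate set when one is given.
    """
    img = as_image(image)
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if combiner not in _COMBINERS:
        raise ValueError(f"combiner must be one of {_COMBINERS}")
    if direction_field is None:
        direction_field = hessian_eigen(img, sigma)
    elif abs(direction_field.sigma - sigma) > 1e-12:
        raise ValueError(
            f"direction_field computed at sigma={direction_field.sigma}, response requested at {sigma}"
        )

    gr = gaussian_derivative(img, sigma, order_y=1)
    gc = gaussian_derivative(img, sigma, order_x=1)
    dr, dc = direction_field.e1[0], direction_field.e1[1]

    h, w = img.shape
    rows, cols = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")

    terms = []
    inbounds = np.ones(img.shape, dtype=bool)
    for sgn in (1.0, -1.0):
        pr = rows + sgn * sigma * dr
        pc = cols + sgn * sigma * dc
        inbounds &= (pr >= 0) & (pr <= h - 1) & (pc >= 0) & (pc <= w - 1)
        # order=1 map_coordinates is exactly bilinear interpolation
        sr = ndimage.map_coordinates(gr, [pr, pc], order=1, mode="nearest")
        sc = ndimage.map_coordinates(gc, [pr, pc], order=1, mode="nearest")
        terms.append(sgn * (sr * dr + sc * dc))
    t1, t2 = terms
    if use_abs:
        t1, t2 = np.abs(t1), np.abs(t2)

    if combiner == "max":
        vals = np.maximum(t1, t2)
    elif combiner == "mean":
        vals = 0.5 * (t1 + t2)
    else:
        vals = np.minimum(t1, t2)
    vals = np.maximum(vals, 0.0)
    vals[~inbounds] = 0.0
    if gate is not None:
        vals = np.where(gate.mask, vals, 0.0)
    return ResponseMap(values=vals, sigma=float(sigma), combiner=combiner, normalized=False)


def normalize_response(response: ResponseMap, gamma: float) -> ResponseMap:
    """Apply the sigma^gamma scale normalization (once).

    gamma = 1 is the neutral first-order normalization; raising it biases
    the multiscale maximum toward thick vessels, lowering it toward thin
    ones.  Normalizing an already-normalized map is a state error.
    """
    if response.normalized:
        raise ValueError("response map is already normalized")
    return replace(
        response,
        values=response.values * response.sigma**gamma,
        normalized=True,
    )


def multiscale_response(
    image: GrayImage,
    scales: ScaleSpec,
    gamma: float = 1.0,
    combiner: str = "max",
    gate: bool = False,
    gate_ratio: float = 0.5,
    gate_quantile: float = 0.25,
    use_abs: bool = False,
) -> MultiscaleResult:
    """Normalized multiscale medialness map with winning-scale bookkeeping.

    Per scale: Hessian eigen-analysis, optional eigenvalue gating,
    offset-gradient response, sigma^gamma normalization.  The pointwise
    maximum over scales is rescaled to [0, 1] by its global maximum
    (an identically zero map stays zero); ``argmax_sigma`` records the
    scale achieving the maximum at each pixel.
    """
    img = as_image(image)
    if scales.n_scales < 1 or len(scales.sigmas) == 0:
        raise ValueError("scale set must be non-empty")
    stack = np.empty((len(scales.sigmas),) + img.shape)
    for i, sigma in enumerate(scales.sigmas):
        hf = hessian_eigen(img, float(sigma))
        cs = preselect_candidates(hf, gate_ratio, gate_quantile) if gate else None
        rm = single_scale_response(img, float(sigma), combiner, hf, cs, use_abs)
        stack[i] = normalize_response(rm, gamma).values
    idx = np.argmax(stack, axis=0)
    resp = np.take_along_axis(stack, idx[None], axis=0)[0]
    peak = resp.max()
    if peak > 0:
        resp = resp / peak
    return MultiscaleResult(
        response=resp,
        argmax_sigma=scales.sigmas[idx],
        gamma=float(gamma),
        sigmas=scales.sigmas.copy(),
        combiner=combiner,
    )
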