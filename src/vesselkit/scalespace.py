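"""Gaussian scale-space derivatives and Hessian eigen-analysis.

For a dark tube on a bright background the Hessian of the Gaussian-smoothed
image H_sigma has, near the tube axis, one large positive eigenvalue whose
eigenvector crosses the tube and one near-zero eigenvalue whose eigenvector
follows the axis.  This module computes scale-space derivatives, the ordered
per-pixel eigen-decomposition (lambda1 >= lambda2), and the preselection of
candidate axis pixels from the eigenvalues.

Derivative kernels are truncated at radius ceil(4*sigma) with replicated
(nearest) borders.  Vector quantities are stored with components ordered
(row, col).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._validation import GrayImage, as_image

__all__ = [
    "gaussian_derivative",
    "HessianField",
    "hessian_eigen",
    "CandidateSet",
    "preselect_candidates",
]


def gaussian_derivative(
    image: GrayImage,
    sigma: float,
    order_x: int = 0,
    order_y: int = 0,
    scale_normalized: bool = False,
) -> GrayImage:
    """Separable Gaussian-derivative convolution at scale ``sigma``.

    ``order_x`` differentiates along columns, ``order_y`` along rows; total
    order up to 2.  With ``scale_normalized`` the result is multiplied by
    ``sigma**(order_x + order_y)`` so derivative magnitudes are comparable
    across scales (first-order normalization of scale-space theory).
    """
    img = as_image(image)
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if order_x < 0 or order_y < 0 or order_x + order_y > 2:
        raise ValueError("derivative orders must be >= 0 with total order <= 2")
    radius = int(np.ceil(4.0 * sigma))
    out = ndimage.gaussian_filter(img, sigma, order=(order_y, order_x), mode="nearest", radius=radius)
    if scale_normalized:
        out = out * sigma ** (order_x + order_y)
    return out


@dataclass
class HessianField:
    """Per-pixel ordered eigen-system of the smoothed Hessian H_sigma.

    ``lambda1 >= lambda2`` everywhere; ``e1``/``e2`` are the associated unit
    eigenvectors stored as arrays of shape ``(2, H, W)`` with components
    (row, col).  Eigenvector signs are fixed so the first nonzero component
    is nonnegative; at exact ties e1=(1,0), e2=(0,1).
    """

    lambda1: np.ndarray
    lambda2: np.ndarray
    e1: np.ndarray
    e2: np.ndarray
    sigma: float


def hessian_eigen(image: GrayImage, sigma: float, scale_normalized: bool = True) -> HessianField:
    """Closed-form 2x2 symmetric eigen-decomposition of H_sigma per pixel.

    ``scale_normalized`` multiplies the second derivatives by sigma^2 (a
    uniform positive factor — eigenvectors and eigenvalue ordering are
    unaffected, but magnitudes become comparable across scales).
    """
    img = as_image(image)
    hrr = gaussian_derivative(img, sigma, order_y=2, scale_normalized=scale_normalized)
    hcc = gaussian_derivative(img, sigma, order_x=2, scale_normalized=scale_normalized)
    hrc = gaussian_derivative(img, sigma, order_x=1, order_y=1, scale_normalized=scale_normalized)

    mean = 0.5 * (hrr + hcc)
    diff = 0.5 * (hrr - hcc)
    disc = np.hypot(diff, hrc)
    lam1 = mean + disc
    lam2 = mean - disc

    # Eigenvector of lam1: both (diff+disc, hrc) and (hrc, disc-diff) are
    # valid; pick per-pixel the better-conditioned branch.
    use_a = diff >= 0
    vr = np.where(use_a, diff + disc, hrc)
    vc = np.where(use_a, hrc, disc - diff)
    norm = np.hypot(vr, vc)
    degenerate = disc <= 1e-9 * np.maximum(np.abs(lam1), np.abs(lam2)) + 1e-300
    safe = np.where(degenerate | (norm == 0), 1.0, norm)
    e1r = np.where(degenerate, 1.0, vr / safe)
    e1c = np.where(degenerate, 0.0, vc / safe)

    # sign convention: first nonzero component nonnegative
    flip = (e1r < 0) | ((e1r == 0) & (e1c < 0))
    e1r = np.where(flip, -e1r, e1r)
    e1c = np.where(flip, -e1c, e1c)

    e2r, e2c = -e1c, e1r
    flip2 = (e2r < 0) | ((e2r == 0) & (e2c < 0))
    e2r = np.where(flip2, -e2r, e2r)
    e2c = np.where(flip2, -e2c, e2c)

    return HessianField(
        lambda1=lam1,
        lambda2=lam2,
        e1=np.stack([e1r, e1c]),
        e2=np.stack([e2r, e2c]),
        sigma=float(sigma),
    )


@dataclass
class CandidateSet:
    """Pixels preselected as likely vessel-axis points, with the thresholds
    that produced them.  ``mask`` is the boolean image; ``coordinates`` the
    (N, 2) array of (row, col) positions, all strictly interior."""

    mask: np.ndarray
    coordinates: np.ndarray
    criterion_params: dict = field(default_factory=dict)


def preselect_candidates(
    hessian: HessianField,
    ratio_threshold: float = 0.5,
    strength_quantile: float = 0.25,
) -> CandidateSet:
    """Select candidate axis pixels of dark tubes from Hessian eigenvalues.

    A pixel qualifies when, for the ideal dark linear structure
    (lambda2 ~ 0 < lambda1):

    * ``lambda1 > 0`` (dark-on-bright polarity; invert the image first for
      bright structures),
    * ``|lambda2| <= ratio_threshold * lambda1`` (elongation), and
    * ``lambda1`` is at or above the ``strength_quantile`` quantile of the
      positive lambda1 population (discards weak curvature responses).

    Border pixels are excluded.  Degenerate images with no positive
    lambda1 yield an empty set, not an error.
    """
    if not 0 < ratio_threshold < 1:
        raise ValueError("ratio_threshold must be in (0, 1)")
    if not 0 < strength_quantile < 1:
        raise ValueError("strength_quantile must be in (0, 1)")
    l1, l2 = hessian.lambda1, hessian.lambda2
    positive = l1 > 0
    cond = positive & (np.abs(l2) <= ratio_threshold * l1)
    if positive.any():
        cond &= l1 >= np.quantile(l1[positive], strength_quantile)
    interior = np.zeros_like(cond)
    interior[1:-1, 1:-1] = True
    cond &= interior
    return CandidateSet(
        mask=cond,
        coordinates=np.argwhere(cond),
        criterion_params={
            "ratio_threshold": ratio_threshold,
            "strength_quantile": strength_quantile,
            "sigma": hessian.sigma,
        },
    )
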