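"""Synthetic vessel phantoms.

Generates the kinds of images the detector is built for: dark tubes with a
Gaussian cross-sectional intensity profile on a bright background, either
straight ("bar") or circular ("ring"), plus flat fields and seeded additive
Gaussian noise.  These phantoms stand in for fundus photographs in every
test: vessels in retinal images are well modelled as dark Gaussian-profile
curvilinear structures on a brighter, roughly homogeneous background.

Conventions
-----------
* Images are float64 arrays indexed ``[row, col]``.
* A tube of *radius* r has cross-section ``background - contrast *
  exp(-d^2 / (2 r^2))`` where ``d`` is the distance to the tube axis, so
  ``radius`` plays the role of the Gaussian scale of the profile (matching
  the detector's radius == scale convention).
* Phantom generation is fully deterministic; only :func:`add_gaussian_noise`
  consumes a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from ._validation import GrayImage, as_image

__all__ = [
    "VesselPhantomSpec",
    "NoiseSpec",
    "make_bar_phantom",
    "make_ring_phantom",
    "add_gaussian_noise",
    "quantize_u8",
    "bar_axis_mask",
    "bar_tube_mask",
    "ring_tube_mask",
]


@dataclass(frozen=True)
class VesselPhantomSpec:
    """Geometry and photometry of a straight Gaussian-profile tube.

    Parameters
    ----------
    radius : float
        Gaussian scale of the cross-section, in pixels (> 0).
    angle_deg : float
        Orientation of the tube axis in degrees; 0 means the axis runs
        along image columns (a horizontal bar), 90 along rows.
    contrast : float
        Depth of the dark tube below the background level (>= 0; 0 gives
        a flat field).
    background : float
        Bright background intensity.
    center : (float, float), optional
        ``(row, col)`` point the axis passes through; image center when
        omitted.
    """

    radius: float
    angle_deg: float = 0.0
    contrast: float = 100.0
    background: float = 200.0
    center: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("radius must be > 0")
        if self.contrast < 0:
            raise ValueError("contrast must be >= 0")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive i.i.d. zero-mean Gaussian noise of std ``sigma`` (intensity
    units), drawn from a generator seeded with ``seed``."""

    sigma: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("noise sigma must be >= 0")


def _axis_geometry(spec: VesselPhantomSpec, height: int, width: int):
    cr, cc = spec.center if spec.center is not None else ((height - 1) / 2.0, (width - 1) / 2.0)
    theta = np.deg2rad(spec.angle_deg)
    # axis direction (row, col); angle 0 -> along columns
    t = np.array([np.sin(theta), np.cos(theta)])
    n = np.array([t[1], -t[0]])  # unit normal
    return (cr, cc), t, n


def make_bar_phantom(spec: VesselPhantomSpec, height: int, width: int) -> GrayImage:
    """Dark straight tube on a bright background.

    The intensity is ``background - contrast * exp(-d^2/(2 radius^2))``
    with ``d`` the perpendicular distance to the axis, so the global
    minimum lies on the pixels nearest the axis.

    Raises
    ------
    ValueError
        If the canvas cannot hold the tube with a 3-radius margin on both
        sides of the axis (measured perpendicular to it).
    """
    if height < 3 or width < 3:
        raise ValueError("phantom canvas must be at least 3x3")
    (cr, cc), t, n = _axis_geometry(spec, height, width)
    margin = 3.0 * spec.radius
    for sgn in (+1.0, -1.0):
        pr, pc = cr + sgn * margin * n[0], cc + sgn * margin * n[1]
        if not (0 <= pr <= height - 1 and 0 <= pc <= width - 1):
            raise ValueError(
                f"axis must lie >= 3*radius ({margin:.1f} px) from every border; "
                f"canvas {height}x{width} is too small for radius {spec.radius}"
            )
    rows, cols = np.meshgrid(np.arange(height, dtype=float), np.arange(width, dtype=float), indexing="ij")
    dist = np.abs((rows - cr) * t[1] - (cols - cc) * t[0])
    return spec.background - spec.contrast * np.exp(-(dist**2) / (2.0 * spec.radius**2))


def make_ring_phantom(
    center: Tuple[float, float],
    ring_radius: float,
    tube_radius: float,
    contrast: float,
    background: float,
    size: int,
    quantize: bool = False,
) -> GrayImage:
    """Dark circular tube (annulus) with Gaussian cross-section.

    The object is rotationally symmetric about ``center`` up to grid
    sampling; it emulates a strongly curved vessel.  ``quantize=True``
    rounds and clips to 8-bit levels, reproducing the setting in which
    the combiner comparison below is usually shown (a 100x100, 8-bit
    synthetic ring).

    Raises
    ------
    ValueError
        If the ring plus a 3-tube-radius band does not fit in the canvas.
    """
    if size < 3:
        raise ValueError("size must be >= 3")
    if ring_radius <= 0 or tube_radius <= 0:
        raise ValueError("ring_radius and tube_radius must be > 0")
    cr, cc = center
    reach = ring_radius + 3.0 * tube_radius
    if min(cr, cc, size - 1 - cr, size - 1 - cc) < reach:
        raise ValueError(
            f"ring of reach {reach:.1f} px does not fit a {size}x{size} canvas at center {center}"
        )
    rows, cols = np.meshgrid(np.arange(size, dtype=float), np.arange(size, dtype=float), indexing="ij")
    rho = np.hypot(rows - cr, cols - cc)
    img = background - contrast * np.exp(-((rho - ring_radius) ** 2) / (2.0 * tube_radius**2))
    if quantize:
        img = quantize_u8(img)
    return img


def add_gaussian_noise(image: GrayImage, noise: NoiseSpec) -> GrayImage:
    """Add seeded i.i.d. zero-mean Gaussian noise of std ``noise.sigma``.

    No clipping or quantization is applied: clipping biases PSNR, so it is
    left as an explicit caller decision (:func:`quantize_u8`).  Equal seeds
    give bit-identical outputs.
    """
    img = as_image(image)
    rng = np.random.default_rng(noise.seed)
    return img + rng.normal(0.0, noise.sigma, size=img.shape)


def quantize_u8(image: GrayImage) -> GrayImage:
    """Round and clip to the 256 integer levels of an 8-bit image,
    returned as float64 for pipeline uniformity."""
    return np.clip(np.rint(np.asarray(image, dtype=np.float64)), 0.0, 255.0)


# ---------------------------------------------------------------------------
# Ground-truth helpers (for recall/ROC tests against known phantom geometry)

def bar_axis_mask(spec: VesselPhantomSpec, height: int, width: int) -> np.ndarray:
    """Boolean mask of the pixels nearest the bar axis (distance <= 0.5)."""
    (cr, cc), t, _ = _axis_geometry(spec, height, width)
    rows, cols = np.meshgrid(np.arange(height, dtype=float), np.arange(width, dtype=float), indexing="ij")
    dist = np.abs((rows - cr) * t[1] - (cols - cc) * t[0])
    return dist <= 0.5


def bar_tube_mask(spec: VesselPhantomSpec, height: int, width: int, half_width: Optional[float] = None) -> np.ndarray:
    """Boolean mask of the tube body: distance to axis <= ``half_width``
    (default: one radius, i.e. the profile above ``contrast*e^{-1/2}``)."""
    hw = spec.radius if half_width is None else half_width
    (cr, cc), t, _ = _axis_geometry(spec, height, width)
    rows, cols = np.meshgrid(np.arange(height, dtype=float), np.arange(width, dtype=float), indexing="ij")
    dist = np.abs((rows - cr) * t[1] - (cols - cc) * t[0])
    return dist <= hw


def ring_tube_mask(
    center: Tuple[float, float], ring_radius: float, tube_radius: float, size: int,
    half_width: Optional[float] = None,
) -> np.ndarray:
    """Boolean mask of the ring tube body (|rho - ring_radius| <= half_width,
    default one tube radius)."""
    hw = tube_radius if half_width is None else half_width
    rows, cols = np.meshgrid(np.arange(size, dtype=float), np.arange(size, dtype=float), indexing="ij")
    rho = np.hypot(rows - center[0], cols - center[1])
    return np.abs(rho - ring_radius) <= hw
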