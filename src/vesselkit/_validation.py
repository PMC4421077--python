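"""Shared argument checking for image-valued inputs."""

from __future__ import annotations

import numpy as np

#: 2D float array of intensities; the currency passed between all stages.
GrayImage = np.ndarray


def as_image(arr, name: str = "image") -> np.ndarray:
    """Coerce ``arr`` to a validated float64 2D intensity array.

    Diffusion and Hessian stencils need interior pixels, so both sides
    must be at least 3 pixels long, and every value must be finite.
    """
    out = np.asarray(arr, dtype=np.float64)
    if out.ndim != 2:
        raise ValueError(f"{name} must be 2D, got shape {out.shape}")
    if out.shape[0] < 3 or out.shape[1] < 3:
        raise ValueError(f"{name} must be at least 3x3, got {out.shape}")
    if not np.all(np.isfinite(out)):
        raise ValueError(f"{name} contains non-finite values")
    return out


def same_shape(a: np.ndarray, b: np.ndarray, what: str = "images") -> None:
    if a.shape != b.shape:
        raise ValueError(f"{what} must have equal shapes: {a.shape} vs {b.shape}")
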