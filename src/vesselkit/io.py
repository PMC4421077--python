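"""Image readers and writers.

Fundus photographs are usually analyzed on the green channel, which gives
the highest vessel/background contrast; :func:`read_image` extracts any
single channel (or a luma gray) from color files and passes grayscale
files through unchanged.  Detector response maps live in [0, 1] and are
serialized as 16-bit grayscale so they are not quantized to 256 levels.
"""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from ._validation import GrayImage

__all__ = [
    "read_image",
    "read_mask",
    "write_image_u8",
    "write_response_u16",
    "read_response_u16",
]

log = logging.getLogger(__name__)

_CHANNELS = {"red": 0, "green": 1, "blue": 2}


def read_image(path, channel: str = "gray") -> GrayImage:
    """Read PNG/TIFF/PPM/GIF as a float 2D intensity array.

    ``channel`` is one of gray/green/red/blue.  Grayscale files pass
    through any channel selector unchanged (with a logged warning when a
    color channel was requested); for color files, ``gray`` is the
    Rec. 601 luma.
    """
    if channel not in ("gray", *_CHANNELS):
        raise ValueError(f"channel must be one of gray/red/green/blue, got {channel!r}")
    try:
        arr = iio.imread(Path(path))
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        if channel != "gray":
            log.warning("%s is single-channel; %r selector passes through", path, channel)
        return arr.astype(np.float64)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        if channel == "gray":
            return arr[:, :, :3].astype(np.float64) @ np.array([0.299, 0.587, 0.114])
        return arr[:, :, _CHANNELS[channel]].astype(np.float64)
    raise OSError(f"unsupported image layout {arr.shape} in {path}")


def read_mask(path) -> np.ndarray:
    """Read a binary mask image; any nonzero pixel counts as foreground."""
    return read_image(path, "gray") > 0


def write_image_u8(path, image: GrayImage) -> None:
    """Write an intensity image as 8-bit grayscale (rounded, clipped)."""
    arr = np.clip(np.rint(np.asarray(image, dtype=np.float64)), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), arr)


def write_response_u16(path, values: np.ndarray) -> None:
    """Write a [0, 1] response map as 16-bit grayscale PNG/TIFF."""
    v = np.asarray(values, dtype=np.float64)
    if v.min() < 0 or v.max() > 1:
        raise ValueError("response values must lie in [0, 1]")
    iio.imwrite(Path(path), np.rint(v * 65535).astype(np.uint16))


def read_response_u16(path) -> np.ndarray:
    """Read a 16-bit response map back to floats in [0, 1]."""
    return read_image(path, "gray") / 65535.0
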