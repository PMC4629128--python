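"""Image containers, conversions and file I/O.

Conventions used throughout the package
---------------------------------------
* Raster images are numpy ``uint8`` arrays indexed ``(row, col)``, 0-based:
  grayscale ``(H, W)``, color ``(H, W, 3)``.
* Binary images are boolean ``(H, W)`` arrays with ``True`` = foreground
  ("white"), i.e. the network structure.
* Vertex coordinates are ``(x, y) = (col, row)``; pixel paths are sequences
  of ``(row, col)`` tuples.
"""

from __future__ import annotations

import numpy as np
import imageio.v3 as iio

from .errors import ParameterError

__all__ = [
    "as_raster",
    "as_binary",
    "to_gray",
    "load_image",
    "save_image",
]

#: ITU-R BT.601 luma weights (R, G, B).
_LUMA = np.array([0.299, 0.587, 0.114])


def as_raster(image) -> np.ndarray:
    """Validate and coerce *image* into a uint8 raster array.

    Accepts 2-D (grayscale) or 3-D with 3 channels (RGB). RGBA input is
    accepted and its alpha channel dropped. Raises :class:`ParameterError`
    for anything else, for images smaller than 3x3 or values outside [0, 255].
    """
    arr = np.asarray(image)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.ndim not in (2, 3) or (arr.ndim == 3 and arr.shape[2] != 3):
        raise ParameterError(
            f"expected (H, W) or (H, W, 3) image, got shape {arr.shape}"
        )
    if arr.shape[0] < 3 or arr.shape[1] < 3:
        raise ParameterError(f"image must be at least 3x3, got {arr.shape[:2]}")
    if arr.dtype != np.uint8:
        if np.issubdtype(arr.dtype, np.floating) or np.issubdtype(arr.dtype, np.integer):
            info_min, info_max = float(arr.min()), float(arr.max())
            if info_min < 0 or info_max > 255:
                raise ParameterError(
                    f"intensities must lie in [0, 255], got [{info_min}, {info_max}]"
                )
            arr = np.rint(arr).astype(np.uint8)
        else:
            raise ParameterError(f"unsupported image dtype {arr.dtype}")
    return arr


def as_binary(mask) -> np.ndarray:
    """Coerce *mask* into a boolean (H, W) foreground mask."""
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ParameterError(f"binary image must be 2-D, got shape {arr.shape}")
    return arr.astype(bool)


def to_gray(image: np.ndarray) -> np.ndarray:
    """Single-channel luma view of *image* (identity for grayscale input)."""
    arr = as_raster(image)
    if arr.ndim == 2:
        return arr
    return np.rint(arr.astype(np.float64) @ _LUMA).clip(0, 255).astype(np.uint8)


def load_image(path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG image from *path* as a uint8 raster."""
    return as_raster(iio.imread(path))


def save_image(path, image) -> None:
    """Write a raster or binary image to *path* (format from the extension).

    Boolean masks are written as 0/255 grayscale.
    """
    arr = np.asarray(image)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    iio.imwrite(path, as_raster(arr))
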