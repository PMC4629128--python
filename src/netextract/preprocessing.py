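"""Smoothing and denoising steps applied before segmentation.

All operators preserve shape, channel count and the global intensity bounds
of their input, and use reflect padding at the borders.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage.restoration import denoise_bilateral, denoise_nl_means

from .errors import ParameterError
from .images import as_raster
from .registry import register

__all__ = ["gaussian_blur", "median_blur", "bilateral_filter", "denoise_nlmeans"]


def _check_kernel(kernel: int) -> int:
    kernel = int(kernel)
    if kernel < 1 or kernel % 2 == 0:
        raise ParameterError(f"kernel size must be odd and >= 1, got {kernel}")
    return kernel


def _per_channel(image: np.ndarray, fn) -> np.ndarray:
    if image.ndim == 2:
        return fn(image)
    return np.dstack([fn(image[:, :, c]) for c in range(image.shape[2])])


def _gaussian_kernel(kernel: int, sigma: float) -> np.ndarray:
    # Sampled, normalized Gaussian; sigma default follows the common
    # kernel-size heuristic sigma = 0.3*((k-1)/2 - 1) + 0.8.
    if sigma <= 0:
        sigma = 0.3 * ((kernel - 1) * 0.5 - 1) + 0.8
    x = np.arange(kernel) - (kernel - 1) / 2
    k = np.exp(-(x**2) / (2 * sigma**2))
    return k / k.sum()


@register("gaussian_blur", "preprocessing")
def gaussian_blur(image, kernel: int = 5, sigma: float = 0.0) -> np.ndarray:
    """Separable Gaussian blur with an odd ``kernel`` size.

    ``sigma <= 0`` derives sigma from the kernel size; ``kernel=1`` is the
    identity.
    """
    image = as_raster(image)
    kernel = _check_kernel(kernel)
    if kernel == 1:
        return image.copy()
    k1d = _gaussian_kernel(kernel, float(sigma))

    def blur(ch):
        out = ndi.correlate1d(ch.astype(np.float64), k1d, axis=0, mode="reflect")
        out = ndi.correlate1d(out, k1d, axis=1, mode="reflect")
        return np.rint(out).clip(0, 255).astype(np.uint8)

    return _per_channel(image, blur)


@register("median_blur", "preprocessing")
def median_blur(image, kernel: int = 5) -> np.ndarray:
    """Median filter with an odd square window; removes speck noise."""
    image = as_raster(image)
    kernel = _check_kernel(kernel)
    if kernel == 1:
        return image.copy()
    return _per_channel(
        image, lambda ch: ndi.median_filter(ch, size=kernel, mode="reflect")
    )


@register("bilateral_filter", "preprocessing")
def bilateral_filter(
    image, diameter: int = 9, sigma_color: float = 75.0, sigma_space: float = 75.0
) -> np.ndarray:
    """Edge-preserving bilateral filter (intensity + spatial Gaussian)."""
    image = as_raster(image)
    diameter = _check_kernel(diameter)
    if sigma_color <= 0 or sigma_space <= 0:
        raise ParameterError("sigma_color and sigma_space must be positive")
    if diameter == 1:
        return image.copy()

    def f(ch):
        out = denoise_bilateral(
            ch.astype(np.float64) / 255.0,
            win_size=diameter,
            sigma_color=sigma_color / 255.0,
            sigma_spatial=sigma_space,
            mode="edge",
        )
        return np.rint(out * 255.0).clip(0, 255).astype(np.uint8)

    return _per_channel(image, f)


@register("denoise", "preprocessing")
def denoise_nlmeans(image, strength: float = 10.0) -> np.ndarray:
    """Non-local-means denoising; ``strength`` is the filter strength h in
    intensity units, 0 is the identity."""
    image = as_raster(image)
    if strength < 0:
        raise ParameterError(f"strength must be >= 0, got {strength}")
    if strength == 0:
        return image.copy()

    def f(ch):
        out = denoise_nl_means(
            ch.astype(np.float64) / 255.0,
            h=strength / 255.0,
            patch_size=7,
            patch_distance=11,
            fast_mode=True,
        )
        return np.rint(out * 255.0).clip(0, 255).astype(np.uint8)

    return _per_channel(image, f)
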