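"""Foreground/background segmentation methods and marker strategies.

Foreground is the *brighter* phase by default ("white" = structure); every
method takes an ``invert`` flag for dark-on-light networks. The marker-based
methods (guided watershed, GrabCut) consume a marker image: an int8 grid
with ``1`` = sure foreground, ``-1`` = sure background, ``0`` = unknown.

Marker strategies start from a binary guess (Otsu's threshold of the input
unless stated otherwise):

* erosion/deletion -- sure foreground is the guess eroded ``iterations``
  times, sure background the complement of the guess dilated equally often;
* distance transform -- sure foreground is the set of pixels whose
  Euclidean distance transform reaches ``fraction`` of the maximum;
* adaptive -- the erosion strategy applied to an adaptive threshold guess.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed as _skimage_watershed

from .errors import DegenerateMarkerError, ParameterError
from .images import as_binary, as_raster, to_gray
from .registry import register

__all__ = [
    "SURE_FG",
    "SURE_BG",
    "UNKNOWN",
    "otsu",
    "adaptive_threshold",
    "marker_erosion",
    "marker_distance_transform",
    "marker_adaptive",
    "watershed",
    "grabcut",
    "external_binary",
]

SURE_FG = 1
SURE_BG = -1
UNKNOWN = 0

_SQUARE3 = np.ones((3, 3), bool)


# -- thresholding ----------------------------------------------------------


@register("otsu", "segmentation")
def otsu(image, invert: bool = False) -> np.ndarray:
    """Global threshold maximizing between-class variance of the histogram.

    Constant images yield an empty foreground.
    """
    gray = to_gray(image)
    if gray.min() == gray.max():
        return np.zeros(gray.shape, bool)
    thr = threshold_otsu(gray)
    fg = gray > thr
    return ~fg if invert else fg


@register("adaptive_threshold", "segmentation")
def adaptive_threshold(
    image, block: int = 51, offset: float = 4.0, invert: bool = False
) -> np.ndarray:
    """Local mean threshold: foreground where the pixel exceeds the mean of
    its ``block`` x ``block`` window by more than ``offset``.

    Invariant under any smooth additive background ramp, which is the point
    of the method.
    """
    gray = to_gray(image)
    block = int(block)
    if block < 3 or block % 2 == 0:
        raise ParameterError(f"block must be odd and >= 3, got {block}")
    if block > min(gray.shape):
        raise ParameterError(
            f"block {block} larger than image {gray.shape}"
        )
    local_mean = ndi.uniform_filter(gray.astype(np.float64), size=block, mode="reflect")
    fg = gray.astype(np.float64) > local_mean + float(offset)
    return ~fg if invert else fg


@register("external_binary", "segmentation")
def external_binary(image, threshold: int = 128) -> np.ndarray:
    """Pass-through for externally segmented images: foreground where the
    luma is >= ``threshold`` (use on 0/255 masks from third-party tools)."""
    return to_gray(image) >= int(threshold)


# -- marker strategies -----------------------------------------------------


def _background_seeds(guess: np.ndarray, iterations: int) -> np.ndarray:
    return ~ndi.binary_dilation(guess, _SQUARE3, iterations=iterations)


def _as_marker(sure_fg, sure_bg, what: str) -> np.ndarray:
    if not sure_fg.any():
        raise DegenerateMarkerError(f"empty sure-foreground after {what}")
    if not sure_bg.any():
        raise DegenerateMarkerError(f"empty sure-background after {what}")
    marker = np.zeros(sure_fg.shape, np.int8)
    marker[sure_bg] = SURE_BG
    marker[sure_fg] = SURE_FG
    return marker


def marker_erosion(binary_guess, iterations: int = 1) -> np.ndarray:
    """Erosion/deletion marker strategy (3x3 structuring element)."""
    guess = as_binary(binary_guess)
    if not guess.any():
        raise DegenerateMarkerError("marker_erosion: empty binary guess")
    iterations = int(iterations)
    if iterations < 0:
        raise ParameterError(f"iterations must be >= 0, got {iterations}")
    if iterations == 0:
        sure_fg = guess.copy()
    else:
        sure_fg = ndi.binary_erosion(guess, _SQUARE3, iterations=iterations)
    return _as_marker(
        sure_fg,
        _background_seeds(guess, max(iterations, 1)),
        f"marker_erosion(iterations={iterations})",
    )


def marker_distance_transform(binary_guess, fraction: float = 0.7) -> np.ndarray:
    """Distance-transform marker strategy: sure foreground where the EDT
    reaches ``fraction`` of its maximum."""
    guess = as_binary(binary_guess)
    if not guess.any():
        raise DegenerateMarkerError("marker_distance_transform: empty binary guess")
    fraction = float(fraction)
    if not 0 < fraction < 1:
        raise ParameterError(f"fraction must be in (0, 1), got {fraction}")
    edt = ndi.distance_transform_edt(guess)
    sure_fg = edt >= fraction * edt.max()
    return _as_marker(
        sure_fg,
        _background_seeds(guess, 2),
        f"marker_distance_transform(fraction={fraction})",
    )


def marker_adaptive(
    image, block: int = 51, offset: float = 4.0, iterations: int = 1
) -> np.ndarray:
    """Erosion marker strategy on an adaptive-threshold guess."""
    return marker_erosion(adaptive_threshold(image, block=block, offset=offset), iterations)


# -- guided watershed ------------------------------------------------------


def watershed(image, marker, compactness: float = 0.3) -> np.ndarray:
    """Marker-controlled compact watershed on the morphological gradient
    of the blurred luma; foreground = basins grown from sure-foreground
    seeds.

    The compactness term adds a quadratic distance-to-seed cost to the
    flood, so a basin claims structures near its own seeds but cannot
    travel far through low-gradient corridors. Structures carrying their
    own foreground seeds are therefore kept reliably (a marker seeding
    every stroke recovers essentially all stroke pixels), while strokes
    whose seeds were lost — e.g. a distance-transform marker seeding
    only the widest cores — fall to the surrounding background basin.
    This locality is what makes the distance-transform marker strategy
    characteristically fragile.
    """
    from .preprocessing import gaussian_blur

    gray = to_gray(gaussian_blur(as_raster(image), kernel=5))
    marker = np.asarray(marker)
    if not (marker == SURE_FG).any() or not (marker == SURE_BG).any():
        raise DegenerateMarkerError("watershed needs both seed classes")
    gradient = ndi.grey_dilation(gray, footprint=_SQUARE3) - ndi.grey_erosion(
        gray, footprint=_SQUARE3
    )
    seeds = np.zeros(gray.shape, np.int32)
    seeds[marker == SURE_BG] = 1
    seeds[marker == SURE_FG] = 2
    labels = _skimage_watershed(gradient, markers=seeds, compactness=compactness)
    return labels == 2


# -- GrabCut ---------------------------------------------------------------


def _pairwise_terms(flat: np.ndarray, shape) -> tuple[list, np.ndarray]:
    """8-neighbour pixel pairs and contrast-sensitive weights.

    Weight of a pair = gamma * exp(-beta * ||z_i - z_j||^2) / dist with beta
    the usual inverse of twice the mean squared neighbour difference.
    """
    h, w = shape
    idx = np.arange(h * w).reshape(h, w)
    pairs, dists = [], []
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        a = idx[max(0, -dr) : h - max(0, dr), max(0, -dc) : w - max(0, dc)]
        b = idx[max(0, dr) : h + min(0, dr) or h, max(0, dc) : w + min(0, dc) or w]
        pairs.append(np.stack([a.ravel(), b.ravel()], axis=1))
        dists.append(np.full(a.size, np.hypot(dr, dc)))
    pairs = np.concatenate(pairs)
    dists = np.concatenate(dists)
    diff2 = ((flat[pairs[:, 0]] - flat[pairs[:, 1]]) ** 2).sum(axis=1)
    beta = 1.0 / max(2.0 * diff2.mean(), 1e-12)
    return pairs, np.exp(-beta * diff2) / dists


def grabcut(
    image,
    marker,
    iterations: int = 5,
    gamma: float = 50.0,
    n_components: int = 3,
    seed: int = 0,
) -> np.ndarray:
    """Iterative graph-cut segmentation initialized from a marker.

    Alternates Gaussian-mixture appearance model estimation for the current
    foreground/background labeling with a minimum s-t cut of the standard
    contrast-sensitive pixel grid energy. Sure pixels stay pinned; only the
    marker's unknown region is re-labeled.
    """
    import igraph
    from sklearn.mixture import GaussianMixture

    image = as_raster(image)
    marker = np.asarray(marker)
    iterations = int(iterations)
    if iterations < 1:
        raise ParameterError(f"iterations must be >= 1, got {iterations}")
    if not (marker == SURE_FG).any() or not (marker == SURE_BG).any():
        raise DegenerateMarkerError("grabcut needs both seed classes")
    unknown = marker == UNKNOWN
    if not unknown.any():
        return marker == SURE_FG

    color = image if image.ndim == 3 else np.dstack([image] * 3)
    flat = color.reshape(-1, 3).astype(np.float64) / 255.0
    h, w = image.shape[:2]
    n = h * w
    pairs, weights = _pairwise_terms(flat, (h, w))
    weights = gamma * weights

    g = igraph.Graph(n + 2)
    source, target = n, n + 1
    unary_edges = np.concatenate(
        [
            np.stack([np.full(n, source), np.arange(n)], axis=1),
            np.stack([np.arange(n), np.full(n, target)], axis=1),
        ]
    )
    g.add_edges(np.concatenate([pairs, unary_edges]).tolist())

    rng = np.random.default_rng(seed)
    alpha = (marker == SURE_FG) | unknown  # unknown starts as foreground
    alpha = alpha.ravel()
    pinned_fg = (marker == SURE_FG).ravel()
    pinned_bg = (marker == SURE_BG).ravel()
    big = 1e9

    def neg_loglik(pixels, labels):
        out = np.empty(n)
        for cls in (0, 1):
            sel = labels if cls else ~labels
            sample = pixels[sel]
            if len(sample) > 20000:  # subsample for the GMM fit
                sample = sample[rng.choice(len(sample), 20000, replace=False)]
            n_distinct = len(np.unique(sample, axis=0))
            gm = GaussianMixture(
                n_components=min(n_components, n_distinct),
                covariance_type="full",
                reg_covar=1e-6,
                random_state=int(seed),
            ).fit(sample)
            if cls:
                out_fg = -gm.score_samples(pixels)
            else:
                out_bg = -gm.score_samples(pixels)
        return out_bg, out_fg

    for _ in range(iterations):
        d_bg, d_fg = neg_loglik(flat, alpha)
        # source (=fg side) capacity: cost of labeling bg; target: cost of fg
        cap_src = np.where(pinned_fg, big, np.where(pinned_bg, 0.0, d_bg))
        cap_tgt = np.where(pinned_bg, big, np.where(pinned_fg, 0.0, d_fg))
        caps = np.concatenate([weights, cap_src, cap_tgt])
        cut = g.st_mincut(source, target, capacity=caps.tolist())
        new_alpha = np.zeros(n, bool)
        fg_side = set(cut.partition[0]) if source in cut.partition[0] else set(cut.partition[1])
        new_alpha[[i for i in fg_side if i < n]] = True
        new_alpha |= pinned_fg
        new_alpha &= ~pinned_bg
        if (new_alpha == alpha).all():
            alpha = new_alpha
            break
        alpha = new_alpha
    return alpha.reshape(h, w)


# -- registered composite steps -------------------------------------------
# Each named step reproduces one row of the method tables: a marker strategy
# feeding the marker-based segmenter, with Otsu's output as the guess.


@register("watershed_de", "segmentation")
def watershed_erosion_step(image, iterations: int = 1, invert: bool = False):
    return watershed(image, marker_erosion(otsu(image, invert=invert), iterations))


@register("watershed_dt", "segmentation")
def watershed_distance_step(image, fraction: float = 0.7, invert: bool = False):
    return watershed(image, marker_distance_transform(otsu(image, invert=invert), fraction))


@register("watershed_ad", "segmentation")
def watershed_adaptive_step(
    image,
    block: int = 51,
    offset: float = 4.0,
    iterations: int = 1,
    invert: bool = False,
):
    gray = image if not invert else 255 - to_gray(image)
    return watershed(gray, marker_adaptive(gray, block, offset, iterations))


@register("grabcut_de", "segmentation")
def grabcut_erosion_step(
    image, iterations: int = 1, gc_iterations: int = 5, invert: bool = False
):
    return grabcut(image, marker_erosion(otsu(image, invert=invert), iterations), gc_iterations)


@register("grabcut_dt", "segmentation")
def grabcut_distance_step(
    image, fraction: float = 0.7, gc_iterations: int = 5, invert: bool = False
):
    return grabcut(
        image, marker_distance_transform(otsu(image, invert=invert), fraction), gc_iterations
    )
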