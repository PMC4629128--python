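"""Guo-Hall two-subiteration thinning.

Reduces a segmented foreground to a one-pixel-wide skeleton while
preserving the 8-connectivity of the foreground and the 4-connectivity of
the background. The two subiterations alternately peel opposite sides of
the foreground; a pixel is deleted when its neighbourhood satisfies the
Guo-Hall conditions

    C(p) = 1,   2 <= min(N1, N2) <= 3,   and the subiteration mask is 0,

with C the crossing number over neighbour pairs, and N1/N2 the two
four-pair counts of occupied neighbour slots. Deletion passes repeat until
a fixed point is reached, so the operation is idempotent.

The loop is fully vectorized over the image (boolean array slicing), which
keeps pure-Python performance practical even for megapixel masks. The image
is implicitly padded with background, so neighbourhood tests at the border
are well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .images import as_binary
from .registry import register

__all__ = ["Skeleton", "guo_hall_thin"]


@dataclass
class Skeleton:
    """A thin skeleton plus the segmentation it came from."""

    mask: np.ndarray
    source: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        self.mask = as_binary(self.mask)
        if self.source is None:
            self.source = self.mask.copy()
        else:
            self.source = as_binary(self.source)


def _subiteration(padded: np.ndarray, first: bool) -> bool:
    """One Guo-Hall deletion pass over *padded* (modified in place)."""
    c = padded[1:-1, 1:-1]
    p2 = padded[:-2, 1:-1]   # N
    p3 = padded[:-2, 2:]     # NE
    p4 = padded[1:-1, 2:]    # E
    p5 = padded[2:, 2:]      # SE
    p6 = padded[2:, 1:-1]    # S
    p7 = padded[2:, :-2]     # SW
    p8 = padded[1:-1, :-2]   # W
    p9 = padded[:-2, :-2]    # NW

    C = (
        (~p2 & (p3 | p4)).astype(np.uint8)
        + (~p4 & (p5 | p6))
        + (~p6 & (p7 | p8))
        + (~p8 & (p9 | p2))
    )
    N1 = (p9 | p2).astype(np.uint8) + (p3 | p4) + (p5 | p6) + (p7 | p8)
    N2 = (p2 | p3).astype(np.uint8) + (p4 | p5) + (p6 | p7) + (p8 | p9)
    N = np.minimum(N1, N2)
    if first:
        m = (p2 | p3 | ~p5) & p4
    else:
        m = (p6 | p7 | ~p9) & p8
    delete = c & (C == 1) & (N >= 2) & (N <= 3) & ~m
    if delete.any():
        c &= ~delete
        return True
    return False


@register("guo_hall", "graph_detection", kind="thin")
def guo_hall_thin(segmented) -> Skeleton:
    """Thin *segmented* to a skeleton; empty input gives an empty skeleton."""
    source = as_binary(segmented)
    padded = np.pad(source, 1)
    while True:
        changed = _subiteration(padded, True)
        changed |= _subiteration(padded, False)
        if not changed:
            break
    return Skeleton(mask=padded[1:-1, 1:-1], source=source)
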