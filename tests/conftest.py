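"""Shared fixtures and fixture-building helpers."""

from __future__ import annotations

import math

import numpy as np
import pytest

from netextract import SpatialGraph, generate_truth_graph, render_graph


def render_stroke(shape, p0, p1, width, fg=220, bg=30):
    """Render a single straight stroke (x, y endpoints) as a uint8 image."""
    g = SpatialGraph()
    g.add_vertex(0, *p0)
    g.add_vertex(1, *p1)
    g.add_edge(0, 1, length=math.dist(p0, p1), width_median=width)
    return render_graph(g, shape=shape, fg=fg, bg=bg)


def random_blobs(rng, shape=(96, 96), n_blobs=6, r_lo=3, r_hi=12):
    """Random disk unions: fixture for thinning topology tests."""
    img = np.zeros(shape, bool)
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    for _ in range(n_blobs):
        r = rng.integers(5, shape[0] - 5)
        c = rng.integers(5, shape[1] - 5)
        rad = rng.integers(r_lo, r_hi)
        img |= (yy - r) ** 2 + (xx - c) ** 2 <= rad**2
    return img


def small_truth(seed=0, n_vertices=7):
    """A small generated spatial graph (fast; for filter/similarity tests)."""
    return generate_truth_graph(
        n_vertices=n_vertices,
        shape=(256, 256),
        margin=28,
        min_separation=40,
        width_range=(3, 7),
        seed=seed,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def path_graph():
    """a - b - c path with known lengths and widths."""
    g = SpatialGraph()
    g.add_vertex(0, 0, 0)
    g.add_vertex(1, 10, 0)
    g.add_vertex(2, 10, 10)
    g.add_edge(0, 1, length=10.0, width_median=4.0)
    g.add_edge(1, 2, length=10.0, width_median=6.0)
    return g


@pytest.fixture
def triangle_with_tail():
    """Triangle 0-1-2 plus pendant path 2-3-4."""
    g = SpatialGraph()
    for i, (x, y) in enumerate([(0, 0), (20, 0), (10, 15), (10, 40), (10, 60)]):
        g.add_vertex(i, x, y)
    g.add_edge(0, 1, length=20.0, width_median=3.0)
    g.add_edge(1, 2, length=18.0, width_median=3.0)
    g.add_edge(0, 2, length=18.0, width_median=3.0)
    g.add_edge(2, 3, length=25.0, width_median=3.0)
    g.add_edge(3, 4, length=20.0, width_median=3.0)
    return g
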