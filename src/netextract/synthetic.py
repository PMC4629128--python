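"""Synthetic ground truth: spatial graphs, renders, and distortions.

This module is the fixture factory for the rendered-image evaluation
protocol. It generates connected planar spatial graphs that emulate
curvilinear biological networks (slime-mould plasmodia, wing venation):
well-separated vertices, degrees mostly 3-4, no grazing-angle junctions,
integer stroke widths. Each graph is drawn as an image that preserves the
vertex positions, edge lengths and edge thicknesses exactly, so the graph
*is* the known ground truth for the image. Three distortions degrade the
ideal renders:

``brightness``
    every edge redrawn at a random intensity, so local contrast varies;
``gradient``
    a linear intensity ramp replaces the background, foreground untouched;
``blur``
    a global Gaussian blur (which makes strokes appear slightly wider).

Truth edge lengths use the same chain metric as graph detection (axial
step 1, diagonal step sqrt(2), i.e. the length of the digitized straight
segment), so a perfect extraction reproduces them exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import Delaunay

from .errors import ParameterError
from .graph import SpatialGraph
from .graph_filters import apply_filters

__all__ = [
    "GroundTruthPair",
    "generate_truth_graph",
    "distort_truth",
    "render_graph",
    "condition_brightness",
    "condition_gradient",
    "condition_blur",
    "build_test_set",
    "distill_truth",
    "chain_length",
    "CONDITIONS",
]

CONDITIONS = ("ideal", "brightness", "gradient", "blur")

#: rendering defaults for the evaluation protocol
DEFAULT_SHAPE = (1024, 1024)
DEFAULT_FG = 220
DEFAULT_BG = 30


def chain_length(p0, p1) -> float:
    """Chain-code length of the digitized straight segment p0-p1.

    Equals max(|dx|, |dy|) + (sqrt(2)-1) * min(|dx|, |dy|): the step count
    of a Bresenham walk with diagonal steps weighted sqrt(2).
    """
    dx = abs(p1[0] - p0[0])
    dy = abs(p1[1] - p0[1])
    return max(dx, dy) + (math.sqrt(2.0) - 1.0) * min(dx, dy)


# -- graph generation ------------------------------------------------------


def _sample_points(rng, n, shape, margin, min_separation):
    lo = (margin, margin)
    hi = (shape[1] - margin, shape[0] - margin)
    if hi[0] <= lo[0] or hi[1] <= lo[1]:
        raise ParameterError("margin leaves no room for vertices")
    points: list[tuple[int, int]] = []
    tries = 0
    max_tries = 400 * n
    while len(points) < n:
        tries += 1
        if tries > max_tries:
            raise ParameterError(
                f"cannot place {n} points with separation {min_separation} "
                f"in {shape} (placed {len(points)})"
            )
        x = int(rng.integers(lo[0], hi[0]))
        y = int(rng.integers(lo[1], hi[1]))
        if all((x - px) ** 2 + (y - py) ** 2 >= min_separation**2 for px, py in points):
            points.append((x, y))
    return points


def _edge_angle(pos, v, u) -> float:
    return math.atan2(pos[u][1] - pos[v][1], pos[u][0] - pos[v][0])


def _min_gap(pos, g, v) -> float:
    """Smallest angular gap between incident edges of v (radians)."""
    nbrs = sorted(g[v])
    if len(nbrs) < 2:
        return 2 * math.pi
    angles = sorted(_edge_angle(pos, v, u) for u in nbrs)
    gaps = [b - a for a, b in zip(angles, angles[1:])]
    gaps.append(2 * math.pi - (angles[-1] - angles[0]))
    return min(gaps)


def _tightest_pair(pos, g, v):
    """The two incident edges forming the smallest angular gap at v."""
    nbrs = sorted(g[v])
    pairs = sorted(
        (u, _edge_angle(pos, v, u)) for u in nbrs
    )
    by_angle = sorted(pairs, key=lambda t: t[1])
    best, best_gap = None, None
    for i in range(len(by_angle)):
        a = by_angle[i]
        b = by_angle[(i + 1) % len(by_angle)]
        gap = (b[1] - a[1]) % (2 * math.pi)
        if best_gap is None or gap < best_gap:
            best_gap, best = gap, (a[0], b[0])
    return best


def _removable(g, v, u, min_degree) -> bool:
    if g.degree(v) <= min_degree or g.degree(u) <= min_degree:
        return False
    g.remove_edge(v, u)
    ok = nx.has_path(g, v, u)
    g.add_edge(v, u)
    return ok


def generate_truth_graph(
    n_vertices: int = 30,
    width_range: tuple[int, int] = (3, 11),
    seed=None,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    margin: int = 60,
    min_separation: float = 90.0,
    max_degree: int = 4,
    min_degree: int = 3,
    min_angle_deg: float = 35.0,
    thin_prob: float = 0.3,
) -> SpatialGraph:
    """Generate a connected planar spatial graph with realistic geometry.

    Vertices are uniform random points under a minimum-separation
    constraint; edges come from the Delaunay triangulation, thinned
    deterministically to respect ``max_degree`` and a minimum angular
    separation at junctions, then randomly (under ``seed``) to diversify
    topology — always preserving connectivity and, where possible,
    ``min_degree``. Per-edge widths are uniform integers from
    ``width_range``; truth lengths use :func:`chain_length`.

    Degrees below 3 are avoided because a degree-2 vertex of a drawn graph
    is geometrically invisible (no junction or endpoint exists at it), so
    no image-based method could recover it.
    """
    if n_vertices < 3:
        raise ParameterError(f"n_vertices must be >= 3, got {n_vertices}")
    wlo, whi = int(width_range[0]), int(width_range[1])
    if wlo < 1 or whi < wlo:
        raise ParameterError(f"bad width_range {width_range}")
    rng = np.random.default_rng(seed)
    points = _sample_points(rng, n_vertices, shape, margin, min_separation)

    tri = Delaunay(np.asarray(points, dtype=float))
    g = nx.Graph()
    g.add_nodes_from(range(len(points)))
    for simplex in tri.simplices:
        for i in range(3):
            a, b = int(simplex[i]), int(simplex[(i + 1) % 3])
            g.add_edge(min(a, b), max(a, b))
    pos = {i: p for i, p in enumerate(points)}

    # deterministic pruning: max degree and junction angle
    min_angle = math.radians(min_angle_deg)
    changed = True
    while changed:
        changed = False
        for v in sorted(g.nodes):
            while g.degree(v) > max_degree or _min_gap(pos, g, v) < min_angle:
                pair = _tightest_pair(pos, g, v)
                if pair is None:
                    break
                # drop the longer edge of the tightest pair when allowed
                order = sorted(
                    pair,
                    key=lambda u: -math.dist(pos[v], pos[u]),
                )
                for u in order:
                    if _removable(g, v, u, min_degree):
                        g.remove_edge(v, u)
                        changed = True
                        break
                else:
                    break

    # random thinning for topological diversity
    candidates = sorted(map(tuple, (sorted(e) for e in g.edges)))
    rng.shuffle(candidates)
    for u, v in candidates:
        if thin_prob > 0 and rng.random() < thin_prob and _removable(g, u, v, min_degree):
            g.remove_edge(u, v)

    if not nx.is_connected(g):  # pragma: no cover - thinning preserves it
        keep = max(nx.connected_components(g), key=lambda c: (len(c), -min(c)))
        g = g.subgraph(keep).copy()

    out = SpatialGraph()
    for v in sorted(g.nodes):
        out.add_vertex(v, x=pos[v][0], y=pos[v][1])
    for u, v in sorted(map(tuple, (sorted(e) for e in g.edges))):
        width = int(rng.integers(wlo, whi + 1))
        out.add_edge(
            u,
            v,
            length=chain_length(pos[u], pos[v]),
            width_median=float(width),
            width_var=0.0,
        )
    return out


#: pipeline used to distill generated graphs into extractor-native truths
DISTILL_MERGE_RADIUS = 15.0


def distill_truth(
    graph: SpatialGraph,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    n_iterations: int = 4,
    fg: int = DEFAULT_FG,
    bg: int = DEFAULT_BG,
) -> SpatialGraph:
    """Distill a generated graph through the extraction operator.

    Applies render -> (Otsu, thin, detect, merge) ``n_iterations`` times.
    The result is a ground truth expressed in the extractor's native
    geometry — junction vertices at skeleton bifurcations, traced pixel
    paths, measured widths — exactly as a truth set obtained by running
    the extractor on real images would be. Rendering such a truth and
    re-extracting it is then a near fixed point, so evaluation scores
    measure pipeline degradation under image distortions rather than the
    display-limited localisation of ideal junction points.
    """
    from .pipeline import PipelineConfig, run_pipeline

    config = PipelineConfig.from_names(
        ["otsu", "guo_hall", "detect_graph"],
        {"detect_graph": {"merge_radius": DISTILL_MERGE_RADIUS}},
    )
    out = graph
    for _ in range(int(n_iterations)):
        image = render_graph(out, shape=shape, fg=fg, bg=bg)
        out = run_pipeline(image, config).final_graph
    return out


def distort_truth(
    graph: SpatialGraph, ops=(), seed=None, delete_fraction: float = 0.0
) -> SpatialGraph:
    """Diversify a truth graph: apply graph filters, then randomly delete
    a fraction of edges while preserving connectivity."""
    out = apply_filters(graph, list(ops))
    if delete_fraction > 0:
        rng = np.random.default_rng(seed)
        g = out.nx.copy()
        edges = sorted((min(u, v), max(u, v), k) for u, v, k in g.edges(keys=True))
        rng.shuffle(edges)
        target = int(round(delete_fraction * len(edges)))
        removed = 0
        for u, v, k in edges:
            if removed >= target:
                break
            if u == v:
                continue
            g.remove_edge(u, v, key=k)
            if nx.has_path(g, u, v):
                removed += 1
            else:
                # deletion would disconnect; put it back
                g.add_edge(u, v, key=k, **graph.nx.edges[u, v, k])
        out = SpatialGraph(g)
    return out


# -- rendering -------------------------------------------------------------


def _paint_segment(canvas, p0, p1, width, intensity):
    """Paint a stroke of the given width along segment p0-p1 (x, y coords).

    Foreground is the set of pixels within (width - 0.2) / 2 of the
    segment; the 0.2 offsets digitization so the re-measured width matches
    the nominal one (see the methods notes). Composition is max, so bright
    strokes dominate at crossings.
    """
    if width <= 0:
        raise ParameterError(f"zero-width edge (width={width})")
    hw = (width - 0.2) / 2.0
    h, w = canvas.shape
    x0, y0 = p0
    x1, y1 = p1
    r0 = max(0, int(math.floor(min(y0, y1) - hw - 1)))
    r1 = min(h, int(math.ceil(max(y0, y1) + hw + 2)))
    c0 = max(0, int(math.floor(min(x0, x1) - hw - 1)))
    c1 = min(w, int(math.ceil(max(x0, x1) + hw + 2)))
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dx, dy = x1 - x0, y1 - y0
    denom = dx * dx + dy * dy
    if denom == 0:
        dist = np.hypot(xx - x0, yy - y0)
    else:
        t = np.clip(((xx - x0) * dx + (yy - y0) * dy) / denom, 0.0, 1.0)
        dist = np.hypot(xx - (x0 + t * dx), yy - (y0 + t * dy))
    sel = dist <= hw
    region = canvas[r0:r1, c0:c1]
    region[sel] = np.maximum(region[sel], intensity)


def _paint_path(canvas, path, width, intensity):
    """Paint a stroke of the given width along a traced pixel path.

    Foreground is every pixel within (width - 0.2) / 2 of the path pixel
    set (path pixels are 8-adjacent, so this is the digitized tube around
    the traced centre line).
    """
    if width <= 0:
        raise ParameterError(f"zero-width edge (width={width})")
    hw = (width - 0.2) / 2.0
    h, w = canvas.shape
    rows = [p[0] for p in path]
    cols = [p[1] for p in path]
    pad = int(math.ceil(hw)) + 1
    r0 = max(0, min(rows) - pad)
    r1 = min(h, max(rows) + pad + 1)
    c0 = max(0, min(cols) - pad)
    c1 = min(w, max(cols) + pad + 1)
    if r0 >= r1 or c0 >= c1:
        return
    local = np.ones((r1 - r0, c1 - c0), bool)
    for r, c in path:
        if r0 <= r < r1 and c0 <= c < c1:
            local[r - r0, c - c0] = False
    dist = ndi.distance_transform_edt(local)
    sel = dist <= hw
    region = canvas[r0:r1, c0:c1]
    region[sel] = np.maximum(region[sel], intensity)


def render_graph(
    graph: SpatialGraph,
    margin: int = 30,
    fg: int = DEFAULT_FG,
    bg: int = DEFAULT_BG,
    shape: tuple[int, int] | None = None,
    edge_intensities: dict | None = None,
) -> np.ndarray:
    """Draw *graph* as a grayscale image, preserving geometry.

    Each edge is a stroke of its ``width_median`` along its traced pixel
    path when one is attached (extracted graphs), otherwise a straight
    stroke between its endpoint coordinates (generated graphs); each
    vertex is a disk of its largest incident width. No anti-aliasing:
    pixels are either painted or background. ``edge_intensities``
    overrides the foreground intensity per edge key ``(u, v, k)`` (used
    by the brightness distortion).
    """
    if fg == bg:
        raise ParameterError("foreground and background intensities must differ")
    if shape is None:
        if graph.n_vertices:
            xs, ys = zip(*(graph.position(v) for v in graph.vertices()))
            shape = (
                int(math.ceil(max(ys))) + margin + 1,
                int(math.ceil(max(xs))) + margin + 1,
            )
        else:
            shape = (2 * margin + 3, 2 * margin + 3)
    canvas = np.full(shape, bg, np.uint8)
    vertex_level: dict = {}
    vertex_width: dict = {}
    for u, v, k, d in sorted(graph.nx.edges(keys=True, data=True)):
        level = fg if edge_intensities is None else edge_intensities[(u, v, k)]
        path = d.get("pixel_path")
        if path is not None and len(path) >= 2:
            _paint_path(canvas, path, d["width_median"], level)
        elif u != v:
            _paint_segment(canvas, graph.position(u), graph.position(v), d["width_median"], level)
        for end in (u, v):
            vertex_level[end] = max(vertex_level.get(end, bg), level)
            vertex_width[end] = max(vertex_width.get(end, 0.0), d["width_median"])
    for v in sorted(graph.vertices()):
        width = vertex_width.get(v, 3.0)
        level = vertex_level.get(v, fg)
        p = graph.position(v)
        # terminal bulb: a degree-1 cap drawn flush with the stroke thins
        # to a skeleton that stops short of the endpoint; enlarging the
        # terminal disk by 2 px makes the skeleton terminate at the
        # endpoint, so the drawing preserves the edge length
        if graph.nx.degree(v) == 1:
            width += 4.0
        _paint_segment(canvas, p, p, width, level)
    return canvas


# -- distortion conditions -------------------------------------------------


def condition_brightness(
    image: np.ndarray, truth: SpatialGraph, lo: int = 60, hi: int = 255, seed=None
) -> np.ndarray:
    """Redraw every edge at a random intensity from [lo, hi] (set I2)."""
    if not 0 <= lo <= hi <= 255:
        raise ParameterError(f"bad brightness range [{lo}, {hi}]")
    rng = np.random.default_rng(seed)
    levels = {
        (u, v, k): int(rng.integers(lo, hi + 1))
        for u, v, k in sorted(truth.nx.edges(keys=True))
    }
    bg = int(image[0, 0])
    return render_graph(truth, shape=image.shape, bg=bg, edge_intensities=levels)


def condition_gradient(image: np.ndarray, lo: int = 0, hi: int = 160) -> np.ndarray:
    """Replace the background with a linear left-right ramp (set I3).

    Background pixels are those carrying the image's corner intensity;
    foreground strokes are left untouched.
    """
    bg = image[0, 0]
    ramp = np.rint(np.linspace(lo, hi, image.shape[1]))
    out = image.copy()
    mask = image == bg
    out[mask] = np.broadcast_to(ramp, image.shape).astype(np.uint8)[mask]
    return out


def condition_blur(image: np.ndarray, sigma: float = 2.0) -> np.ndarray:
    """Global Gaussian blur (set I4); strokes appear slightly wider."""
    if sigma < 0:
        raise ParameterError(f"sigma must be >= 0, got {sigma}")
    blurred = ndi.gaussian_filter(image.astype(np.float64), sigma, mode="reflect")
    return np.rint(blurred).clip(0, 255).astype(np.uint8)


# -- test sets -------------------------------------------------------------


@dataclass
class GroundTruthPair:
    """A ground-truth graph, its rendered image and the distortion used."""

    truth: SpatialGraph
    image: np.ndarray
    condition: str
    seed: int


def build_test_set(
    n_images: int = 50,
    condition: str = "ideal",
    params: dict | None = None,
    seed: int = 0,
    generator: dict | None = None,
    distill_iterations: int = 4,
) -> list[GroundTruthPair]:
    """Generate ``n_images`` independent truth/image pairs.

    Each truth graph is generated, then distilled through the extraction
    operator (:func:`distill_truth`) so it carries extractor-native
    geometry, then rendered; the chosen distortion is applied to the
    render. Per-image seeds derive deterministically from the master
    *seed*, so the same seed reproduces the identical set, and different
    conditions built from the same seed share the same underlying truth
    graphs. ``distill_iterations=0`` uses the raw generated graphs.
    """
    if condition not in CONDITIONS:
        raise ParameterError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    params = dict(params or {})
    generator = dict(generator or {})
    shape = generator.pop("shape", DEFAULT_SHAPE)
    fg = params.pop("fg", DEFAULT_FG)
    bg = params.pop("bg", DEFAULT_BG)
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n_images):
        gseed = int(rng.integers(2**31 - 1))
        cseed = int(rng.integers(2**31 - 1))
        truth = generate_truth_graph(seed=gseed, shape=shape, **generator)
        if distill_iterations:
            truth = distill_truth(
                truth, shape=shape, n_iterations=distill_iterations, fg=fg, bg=bg
            )
        image = render_graph(truth, shape=shape, fg=fg, bg=bg)
        if condition == "brightness":
            image = condition_brightness(image, truth, seed=cseed, **params)
        elif condition == "gradient":
            image = condition_gradient(image, **params)
        elif condition == "blur":
            image = condition_blur(image, **params)
        pairs.append(GroundTruthPair(truth=truth, image=image, condition=condition, seed=gseed))
    return pairs
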