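"""Graph filters: largest component, degree-2 smoothing, cycle filter."""

import itertools

import networkx as nx
import numpy as np
import pytest

from netextract import (
    SpatialGraph,
    apply_filters,
    keep_cycles,
    keep_largest_component,
    smooth_degree_two,
)
from conftest import small_truth

FILTERS = {
    "largest": keep_largest_component,
    "smooth": smooth_degree_two,
    "cycles": keep_cycles,
}


def brute_force_bridges(g: nx.MultiGraph):
    """An edge is a bridge iff removing it disconnects its component."""
    bridges = set()
    for u, v, k in g.edges(keys=True):
        if u == v:
            continue
        h = g.copy()
        h.remove_edge(u, v, key=k)
        if not nx.has_path(h, u, v):
            bridges.add((u, v, k))
    return bridges


def random_spatial_graph(seed, n=9, p=0.3):
    rng = np.random.default_rng(seed)
    g = SpatialGraph()
    pts = rng.integers(0, 200, size=(n, 2))
    for i, (x, y) in enumerate(pts):
        g.add_vertex(i, float(x), float(y))
    for i, j in itertools.combinations(range(n), 2):
        if rng.random() < p:
            g.add_edge(i, j, length=float(np.hypot(*(pts[i] - pts[j])) + 1), width_median=3.0)
    if rng.random() < 0.3:
        g.add_edge(0, 0, length=5.0)  # self-loop
    if g.n_edges and rng.random() < 0.4:
        u, v, k, d = next(iter(g.nx.edges(keys=True, data=True)))
        if u != v:
            g.add_edge(u, v, length=d["length"] + 2)  # parallel edge
    return g


class TestLargestComponent:
    def test_triangle_beats_path(self, triangle_with_tail):
        g = triangle_with_tail
        g.add_vertex(10, 100, 100)
        g.add_vertex(11, 120, 100)
        g.add_edge(10, 11, length=20.0)
        out = keep_largest_component(g)
        assert sorted(out.nx.nodes) == [0, 1, 2, 3, 4]

    def test_connected_graph_unchanged(self, triangle_with_tail):
        out = keep_largest_component(triangle_with_tail)
        assert out.is_isomorphic_to(triangle_with_tail)

    def test_tie_breaks_on_lexicographic_coordinate(self):
        g = SpatialGraph()
        # two 2-vertex/1-edge components; the one holding the smaller
        # (x, y) coordinate wins
        g.add_vertex(0, 50.0, 1.0)
        g.add_vertex(1, 60.0, 1.0)
        g.add_vertex(2, 5.0, 90.0)
        g.add_vertex(3, 9.0, 90.0)
        g.add_edge(0, 1, length=10.0)
        g.add_edge(2, 3, length=4.0)
        out = keep_largest_component(g)
        assert sorted(out.nx.nodes) == [2, 3]

    def test_empty_graph(self):
        out = keep_largest_component(SpatialGraph())
        assert out.n_vertices == 0


class TestSmoothing:
    def test_path_contracts_to_single_edge(self, path_graph):
        out = smooth_degree_two(path_graph)
        assert sorted(out.nx.nodes) == [0, 2]
        (u, v, k, d), = out.nx.edges(keys=True, data=True)
        assert d["length"] == pytest.approx(20.0)

    def test_triangle_never_gains_parallel_edges(self):
        g = SpatialGraph()
        for i, (x, y) in enumerate([(0, 0), (10, 0), (5, 8)]):
            g.add_vertex(i, x, y)
        g.add_edge(0, 1, length=10.0)
        g.add_edge(1, 2, length=9.0)
        g.add_edge(0, 2, length=9.0)
        out = smooth_degree_two(g)
        pair_counts = {}
        for u, v in out.nx.edges():
            key = frozenset((u, v))
            pair_counts[key] = pair_counts.get(key, 0) + 1
        assert all(c == 1 for c in pair_counts.values())
        assert out.total_length() == pytest.approx(28.0)

    def test_degree_three_untouched(self, triangle_with_tail):
        out = smooth_degree_two(triangle_with_tail)
        assert 2 in out.nx.nodes  # the degree-3 vertex survives

    @pytest.mark.parametrize("seed", range(10))
    def test_total_length_conserved_exactly(self, seed):
        g = random_spatial_graph(seed)
        out = smooth_degree_two(g)
        assert out.total_length() == pytest.approx(g.total_length(), abs=1e-9)

    def test_widths_recomputed_from_concatenated_diameters(self):
        g = SpatialGraph()
        g.add_vertex(0, 0, 0)
        g.add_vertex(1, 4, 0)
        g.add_vertex(2, 8, 0)
        g.add_edge(0, 1, length=4.0, width_median=3.0,
                   pixel_path=[(0, 0), (0, 2), (0, 4)], diameters=[3.0, 3.0, 3.0])
        g.add_edge(1, 2, length=4.0, width_median=9.0,
                   pixel_path=[(0, 4), (0, 6), (0, 8)], diameters=[9.0, 9.0, 9.0])
        out = smooth_degree_two(g)
        (_, _, _, d), = out.nx.edges(keys=True, data=True)
        # median of pooled diameters, not mean of medians
        assert d["width_median"] == pytest.approx(np.median([3, 3, 3, 9, 9, 9]))
        assert d["width_var"] == pytest.approx(np.var([3, 3, 3, 9, 9, 9]))
        assert d["pixel_path"][0] == (0, 0) and d["pixel_path"][-1] == (0, 8)


class TestCycleFilter:
    def test_pendant_path_removed(self, triangle_with_tail):
        out = keep_cycles(triangle_with_tail)
        assert sorted(out.nx.nodes) == [0, 1, 2]
        assert out.n_edges == 3

    def test_tree_becomes_empty(self):
        g = SpatialGraph()
        for i in range(5):
            g.add_vertex(i, i * 10.0, 0.0)
        for i in range(4):
            g.add_edge(i, i + 1, length=10.0)
        out = keep_cycles(g)
        assert out.n_vertices == 0 and out.n_edges == 0

    def test_two_triangles_bridge_removed(self):
        g = SpatialGraph()
        for i, (x, y) in enumerate(
            [(0, 0), (10, 0), (5, 8), (40, 0), (50, 0), (45, 8)]
        ):
            g.add_vertex(i, x, y)
        for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
            g.add_edge(a, b, length=10.0)
        g.add_edge(2, 5, length=40.0)  # the bridge
        out = keep_cycles(g)
        assert out.n_edges == 6 and out.n_vertices == 6
        assert not out.nx.has_edge(2, 5)

    def test_self_loops_and_parallel_edges_count_as_cycles(self):
        g = SpatialGraph()
        g.add_vertex(0, 0, 0)
        g.add_vertex(1, 10, 0)
        g.add_edge(0, 0, length=6.0)
        g.add_edge(0, 1, length=10.0)
        g.add_edge(0, 1, length=12.0)
        out = keep_cycles(g)
        assert out.n_edges == 3

    @pytest.mark.parametrize("seed", range(10))
    def test_output_matches_bridge_oracle_and_min_degree(self, seed):
        g = random_spatial_graph(seed)
        out = keep_cycles(g)
        # oracle: surviving edges = non-bridges with both endpoints kept
        bridges = brute_force_bridges(g.nx)
        expected = {
            (u, v, k) for u, v, k in g.nx.edges(keys=True) if (u, v, k) not in bridges
        }
        got = set(out.nx.edges(keys=True))
        assert {frozenset((u, v)) for u, v, _ in got} == {
            frozenset((u, v)) for u, v, _ in expected
        }
        assert not brute_force_bridges(out.nx)
        for v in out.nx.nodes:
            loops = out.nx.number_of_edges(v, v)
            assert out.nx.degree(v) >= 2 or loops  # self-loops count twice
        assert all(out.nx.degree(v) >= 2 for v in out.nx.nodes)


class TestComposition:
    def test_empty_list_is_identity(self, triangle_with_tail):
        out = apply_filters(triangle_with_tail, [])
        assert out.is_isomorphic_to(triangle_with_tail)

    def test_names_resolve_to_registered_filters(self, triangle_with_tail):
        out = apply_filters(triangle_with_tail, ["keep_cycles"])
        assert out.is_isomorphic_to(keep_cycles(triangle_with_tail))

    @pytest.mark.parametrize("seed", range(6))
    def test_largest_then_cycles_is_subgraph_of_cycles(self, seed):
        g = random_spatial_graph(seed)
        combined = apply_filters(g, [keep_largest_component, keep_cycles])
        cycles_only = keep_cycles(g)

        def canon(graph):
            return {(min(u, v), max(u, v), k) for u, v, k in graph.nx.edges(keys=True)}

        assert canon(combined) <= canon(cycles_only)

    def test_filter_order_matters(self):
        # component A: big tree (5 vertices); component B: triangle.
        g = SpatialGraph()
        for i, (x, y) in enumerate(
            [(0, 0), (10, 0), (20, 0), (30, 0), (40, 0), (100, 0), (110, 0), (105, 8)]
        ):
            g.add_vertex(i, x, y)
        for a, b in [(0, 1), (1, 2), (2, 3), (3, 4)]:
            g.add_edge(a, b, length=10.0)
        for a, b in [(5, 6), (6, 7), (5, 7)]:
            g.add_edge(a, b, length=10.0)
        largest_then_cycles = apply_filters(g, [keep_largest_component, keep_cycles])
        cycles_then_largest = apply_filters(g, [keep_cycles, keep_largest_component])
        assert largest_then_cycles.n_edges == 0
        assert cycles_then_largest.n_edges == 3


@pytest.mark.parametrize("name", FILTERS)
@pytest.mark.parametrize("seed", range(5))
def test_filters_idempotent(name, seed):
    g = random_spatial_graph(seed)
    f = FILTERS[name]
    once = f(g)
    twice = f(once)
    assert twice.is_isomorphic_to(once)


@pytest.mark.parametrize("name", ["largest", "cycles"])
def test_filters_are_subgraphs_with_fixed_coordinates(name):
    g = random_spatial_graph(3)
    out = FILTERS[name](g)
    for v in out.nx.nodes:
        assert out.position(v) == g.position(v)
    assert set(out.nx.edges(keys=True)) <= set(g.nx.edges(keys=True))


def test_filters_on_extracted_graph():
    """Cycle filter applied to a real extraction keeps only the reticulate
    core (minimum degree 2, no bridges)."""
    from netextract import detect_graph, guo_hall_thin, render_graph
    from netextract.segmentation import otsu

    g = small_truth(seed=2)
    img = render_graph(g, shape=(256, 256))
    seg = otsu(img)
    extracted = detect_graph(guo_hall_thin(seg), seg, merge_radius=6)
    out = keep_cycles(extracted)
    assert out.n_edges > 0
    assert not brute_force_bridges(out.nx)
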