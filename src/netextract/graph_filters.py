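"""Graph filters: post-detection cleanup operating purely on the graph.

Artifacts from segmentation or thinning are removed *after* the graph is
established, never by editing the segmented image or skeleton. All filters
are idempotent and return a new graph; surviving vertices keep their
coordinates.
"""

from __future__ import annotations

import numpy as np
import networkx as nx

from .graph import SpatialGraph
from .registry import register

__all__ = [
    "keep_largest_component",
    "smooth_degree_two",
    "keep_cycles",
    "apply_filters",
]


@register("keep_largest_component", "graph_filtering")
def keep_largest_component(graph: SpatialGraph) -> SpatialGraph:
    """Keep only the connected component with the most vertices.

    Ties break on edge count, then on the smallest lexicographic vertex
    coordinate, so the result is deterministic.
    """
    if graph.n_vertices == 0:
        return graph.copy()

    def rank(comp):
        sub = graph.nx.subgraph(comp)
        best_coord = min((graph.nx.nodes[v]["x"], graph.nx.nodes[v]["y"]) for v in comp)
        return (-len(comp), -sub.number_of_edges(), best_coord)

    best = min(nx.connected_components(graph.nx), key=rank)
    return SpatialGraph(nx.MultiGraph(graph.nx.subgraph(best).copy()))


def _concat_paths(p1, p2, via):
    """Concatenate two pixel paths so they run endpoint-via-endpoint."""
    if p1 is None or p2 is None:
        return None
    p1 = list(p1) if p1[-1] == via else list(p1)[::-1]
    p2 = list(p2) if p2[0] == via else list(p2)[::-1]
    return p1 + p2[1:]


def _concat_diams(e1, e2):
    d1, d2 = e1.get("diameters"), e2.get("diameters")
    if d1 is None or d2 is None:
        return None
    return np.concatenate([np.asarray(d1), np.asarray(d2)])


@register("smooth_degree_two", "graph_filtering")
def smooth_degree_two(graph: SpatialGraph) -> SpatialGraph:
    """Contract degree-2 vertices unless that would create a parallel edge.

    The replacement edge's length is the exact sum of the two lengths; its
    width statistics are recomputed from the concatenated per-pixel
    diameters when those were kept, otherwise approximated by a
    length-weighted mean (medians do not compose exactly). Vertices on
    self-loops are never smoothed. Applied to a fixed point, processing
    vertices in ascending id order.
    """
    g = graph.nx.copy()
    changed = True
    while changed:
        changed = False
        for v in sorted(g.nodes):
            if g.degree(v) != 2:
                continue
            inc = list(g.edges(v, keys=True, data=True))
            if len(inc) != 2:  # a self-loop contributes degree 2 via one edge
                continue
            (_, a, _, d1), (_, b, _, d2) = inc
            if a == v or b == v or a == b:
                continue
            if g.has_edge(a, b):
                continue  # contraction would introduce a parallel edge
            length = d1["length"] + d2["length"]
            diams = _concat_diams(d1, d2)
            if diams is not None:
                width_median = float(np.median(diams))
                width_var = float(np.var(diams))
            else:
                width_median = (
                    d1["length"] * d1["width_median"] + d2["length"] * d2["width_median"]
                ) / length
                width_var = (
                    d1["length"] * d1["width_var"] + d2["length"] * d2["width_var"]
                ) / length
            attrs = dict(
                length=length, width_median=width_median, width_var=width_var
            )
            vpix = (int(round(g.nodes[v]["y"])), int(round(g.nodes[v]["x"])))
            path = _concat_paths(d1.get("pixel_path"), d2.get("pixel_path"), vpix)
            if path is not None:
                attrs["pixel_path"] = path
            if diams is not None:
                attrs["diameters"] = diams
            g.remove_node(v)
            g.add_edge(a, b, **attrs)
            changed = True
    return SpatialGraph(g)


@register("keep_cycles", "graph_filtering")
def keep_cycles(graph: SpatialGraph) -> SpatialGraph:
    """Remove every vertex and edge not contained in any cycle.

    An edge survives iff it is not a bridge (self-loops and parallel pairs
    count as cycles); vertices survive iff an incident edge does. This
    deletes dead-ends and trees entirely.
    """
    g = graph.nx.copy()
    simple = nx.Graph()
    simple.add_nodes_from(g.nodes)
    multiplicity: dict[tuple, int] = {}
    for u, v in g.edges():
        if u == v:
            continue
        key = (min(u, v), max(u, v))
        multiplicity[key] = multiplicity.get(key, 0) + 1
        simple.add_edge(*key)
    bridges = {
        (u, v)
        for u, v in nx.bridges(simple)
        if multiplicity[(min(u, v), max(u, v))] == 1
    }
    doomed = [
        (u, v, k)
        for u, v, k in g.edges(keys=True)
        if u != v and ((u, v) in bridges or (v, u) in bridges)
    ]
    g.remove_edges_from(doomed)
    g.remove_nodes_from([v for v in list(g.nodes) if g.degree(v) == 0])
    return SpatialGraph(g)


def apply_filters(graph: SpatialGraph, filters) -> SpatialGraph:
    """Left-to-right composition of graph filters.

    *filters* is a sequence of callables or registered step names; the
    empty list is the identity.
    """
    from .registry import get_step

    out = graph
    for f in filters:
        if callable(f):
            out = f(out)
        else:
            step = get_step(str(f))
            if step.stage != "graph_filtering":
                raise ValueError(f"{f!r} is not a graph filter")
            out = step.func(out)
    return out
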