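"""The spatial multigraph container and graph file I/O.

A :class:`SpatialGraph` is an undirected multigraph whose vertices carry
pixel coordinates (``x`` = column, ``y`` = row) and whose edges carry a
length in path units (axial step = 1, diagonal step = sqrt(2)), a width
median and width variance in pixels, and optionally the traced pixel path
and the per-pixel diameter samples it was measured from.

Storage is a thin wrapper around :class:`networkx.MultiGraph`; the wrapped
graph is available as the ``nx`` attribute for analysis with the usual
networkx toolchain.
"""

from __future__ import annotations

from typing import Iterator

import networkx as nx
import numpy as np

from .errors import GraphIntegrityError

__all__ = [
    "SpatialGraph",
    "write_graphml",
    "read_graphml",
    "write_gml",
    "read_gml",
    "write_edgelist",
    "read_edgelist",
]

#: Edge attributes serialized to GraphML/GML/edge-list files.
_EDGE_ATTRS = ("length", "width_median", "width_var")


class SpatialGraph:
    """Undirected spatial multigraph with geometric edge attributes."""

    def __init__(self, graph: nx.MultiGraph | None = None):
        self.nx: nx.MultiGraph = graph if graph is not None else nx.MultiGraph()

    # -- construction -----------------------------------------------------

    def add_vertex(self, vid, x: float, y: float) -> None:
        self.nx.add_node(vid, x=float(x), y=float(y))

    def add_edge(
        self,
        u,
        v,
        length: float,
        width_median: float = 0.0,
        width_var: float = 0.0,
        pixel_path=None,
        diameters=None,
    ):
        """Add an edge; returns the multigraph key."""
        if u not in self.nx or v not in self.nx:
            raise GraphIntegrityError(f"edge ({u}, {v}) has a dangling endpoint")
        if length <= 0:
            raise GraphIntegrityError(f"edge ({u}, {v}) has non-positive length {length}")
        attrs = dict(
            length=float(length),
            width_median=float(width_median),
            width_var=float(width_var),
        )
        if pixel_path is not None:
            attrs["pixel_path"] = [tuple(p) for p in pixel_path]
        if diameters is not None:
            attrs["diameters"] = np.asarray(diameters, dtype=float)
        return self.nx.add_edge(u, v, **attrs)

    # -- inspection -------------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return self.nx.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.nx.number_of_edges()

    def position(self, vid) -> tuple[float, float]:
        d = self.nx.nodes[vid]
        return (d["x"], d["y"])

    def positions(self) -> dict:
        return {v: (d["x"], d["y"]) for v, d in self.nx.nodes(data=True)}

    def vertices(self) -> Iterator:
        return iter(self.nx.nodes)

    def edges(self, data: bool = False):
        return self.nx.edges(keys=True, data=data)

    def total_length(self) -> float:
        return sum(d["length"] for *_, d in self.nx.edges(keys=True, data=True))

    def copy(self) -> "SpatialGraph":
        return SpatialGraph(self.nx.copy())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"SpatialGraph({self.n_vertices} vertices, {self.n_edges} edges)"

    def is_isomorphic_to(self, other: "SpatialGraph") -> bool:
        """Structural equality including coordinates (used in round-trip tests)."""
        a, b = self.nx, other.nx
        if sorted(a.nodes) != sorted(b.nodes):
            return False
        for v in a.nodes:
            if not np.allclose(
                [a.nodes[v]["x"], a.nodes[v]["y"]],
                [b.nodes[v]["x"], b.nodes[v]["y"]],
            ):
                return False

        def key(item):
            u, v, _, d = item
            uu, vv = sorted((u, v))
            return (uu, vv, round(d["length"], 9), round(d["width_median"], 9))

        ea = sorted(a.edges(keys=True, data=True), key=key)
        eb = sorted(b.edges(keys=True, data=True), key=key)
        if len(ea) != len(eb):
            return False
        for x, y in zip(ea, eb):
            if key(x) != key(y):
                return False
            if not np.isclose(x[3]["width_var"], y[3]["width_var"]):
                return False
        return True


# -- serialization ---------------------------------------------------------
#
# GraphML and GML carry the scalar attributes only (x, y per vertex; length,
# width_median, width_var per edge); pixel paths are an in-memory detail.


def _scalar_copy(g: SpatialGraph) -> nx.MultiGraph:
    out = nx.MultiGraph()
    for v, d in g.nx.nodes(data=True):
        out.add_node(v, x=float(d["x"]), y=float(d["y"]))
    for u, v, k, d in g.nx.edges(keys=True, data=True):
        out.add_edge(u, v, key=k, **{a: float(d[a]) for a in _EDGE_ATTRS})
    return out


def _relabel_ints(g: nx.MultiGraph) -> nx.MultiGraph:
    try:
        mapping = {v: int(v) for v in g.nodes}
    except (TypeError, ValueError):
        return g
    return nx.relabel_nodes(g, mapping)


def write_graphml(graph: SpatialGraph, path) -> None:
    nx.write_graphml(_scalar_copy(graph), path)


def read_graphml(path) -> SpatialGraph:
    g = nx.read_graphml(path, force_multigraph=True)
    return SpatialGraph(_relabel_ints(nx.MultiGraph(g)))


def write_gml(graph: SpatialGraph, path) -> None:
    nx.write_gml(_scalar_copy(graph), path)


def read_gml(path) -> SpatialGraph:
    g = nx.read_gml(path, label="id")
    return SpatialGraph(_relabel_ints(nx.MultiGraph(g)))


def write_edgelist(graph: SpatialGraph, path) -> None:
    """Plain-text vertex/edge list.

    Lines: ``v id x y`` for vertices, ``e u v key length width_median
    width_var`` for edges; ``#`` starts a comment.
    """
    with open(path, "w") as fh:
        fh.write("# netextract graph v1\n")
        fh.write("# v id x y\n")
        for v, d in sorted(graph.nx.nodes(data=True)):
            fh.write(f"v {v} {d['x']:.6g} {d['y']:.6g}\n")
        fh.write("# e u v key length width_median width_var\n")
        for u, v, k, d in sorted(graph.nx.edges(keys=True, data=True)):
            fh.write(
                f"e {u} {v} {k} {d['length']:.9g} "
                f"{d['width_median']:.9g} {d['width_var']:.9g}\n"
            )


def read_edgelist(path) -> SpatialGraph:
    g = SpatialGraph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            try:
                if parts[0] == "v":
                    g.add_vertex(int(parts[1]), float(parts[2]), float(parts[3]))
                elif parts[0] == "e":
                    g.nx.add_edge(
                        int(parts[1]),
                        int(parts[2]),
                        key=int(parts[3]),
                        length=float(parts[4]),
                        width_median=float(parts[5]),
                        width_var=float(parts[6]),
                    )
                else:
                    raise ValueError(f"unknown record type {parts[0]!r}")
            except (IndexError, ValueError) as exc:
                raise GraphIntegrityError(f"{path}:{lineno}: {exc}") from exc
    return g
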