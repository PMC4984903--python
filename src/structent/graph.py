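"""Weighted undirected graphs and one-dimensional structural entropy.

The one-dimensional structural entropy of a connected graph is the Shannon
entropy of the stationary distribution of a random walk on it,

    H1(G) = -sum_v (d_v / vol) * log2(d_v / vol),

where ``d_v`` is the weighted degree of vertex ``v`` and ``vol`` the graph
volume (sum of all degrees).  For a disconnected graph the entropy is the
volume-weighted average of the component entropies; isolated vertices carry
zero volume and therefore contribute nothing, and a single edgeless vertex
has entropy 0 by convention (no random walk can occur).

The closed form above is a reconstruction from the prose definition of the
stationary-distribution encoding (the displayed equation is not reproduced
in the source text); it is cross-validated against the partition/tree forms
in :mod:`structent.tree`.
"""

from __future__ import annotations

from collections import deque
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "DegenerateGraphError",
    "WeightedGraph",
    "stationary_distribution",
    "one_dim_entropy",
    "read_edge_list",
    "write_edge_list",
]


class DegenerateGraphError(ValueError):
    """Raised when an operation requires a graph with positive volume."""


class WeightedGraph:
    """Undirected graph with strictly positive edge weights.

    Vertices keep their insertion order; that order is the global
    tie-breaking order for every downstream algorithm.  Self-loops,
    duplicate edges and non-positive weights are rejected at construction.
    """

    def __init__(self, vertices: Iterable[str] = ()):
        self._labels: list[str] = []
        self._index: dict[str, int] = {}
        self._adj: list[dict[int, float]] = []
        for v in vertices:
            self.add_vertex(v)

    # -- construction -----------------------------------------------------

    def add_vertex(self, label: str) -> int:
        if label in self._index:
            raise ValueError(f"duplicate vertex label: {label!r}")
        idx = len(self._labels)
        self._labels.append(label)
        self._index[label] = idx
        self._adj.append({})
        return idx

    def add_edge(self, u: str, v: str, weight: float) -> None:
        if u == v:
            raise ValueError(f"self-loop rejected: {u!r}")
        if not weight > 0:
            raise ValueError(f"edge ({u!r}, {v!r}) has non-positive weight {weight}")
        iu = self._index.get(u)
        iv = self._index.get(v)
        if iu is None:
            iu = self.add_vertex(u)
        if iv is None:
            iv = self.add_vertex(v)
        if iv in self._adj[iu]:
            raise ValueError(f"duplicate edge ({u!r}, {v!r})")
        self._adj[iu][iv] = float(weight)
        self._adj[iv][iu] = float(weight)

    # -- queries ----------------------------------------------------------

    @property
    def vertex_labels(self) -> list[str]:
        return list(self._labels)

    @property
    def n_vertices(self) -> int:
        return len(self._labels)

    @property
    def n_edges(self) -> int:
        return sum(len(a) for a in self._adj) // 2

    def index_of(self, label: str) -> int:
        return self._index[label]

    def has_edge(self, u: str, v: str) -> bool:
        iu, iv = self._index.get(u), self._index.get(v)
        return iu is not None and iv is not None and iv in self._adj[iu]

    def edge_weight(self, u: str, v: str) -> float:
        return self._adj[self._index[u]][self._index[v]]

    def neighbors(self, idx: int) -> dict[int, float]:
        """Adjacency of vertex ``idx`` as ``{neighbor_index: weight}``."""
        return self._adj[idx]

    def degree(self, v: str) -> float:
        return sum(self._adj[self._index[v]].values())

    def degrees(self) -> np.ndarray:
        """Weighted degree of every vertex, in vertex order."""
        return np.array([sum(a.values()) for a in self._adj], dtype=float)

    @property
    def volume(self) -> float:
        return float(sum(sum(a.values()) for a in self._adj))

    def edges(self) -> Iterator[tuple[str, str, float]]:
        for iu, adj in enumerate(self._adj):
            for iv, w in adj.items():
                if iu < iv:
                    yield self._labels[iu], self._labels[iv], w

    def connected_components(self) -> list[list[int]]:
        """Vertex-index components in order of smallest contained index."""
        seen = [False] * len(self._labels)
        comps: list[list[int]] = []
        for start in range(len(self._labels)):
            if seen[start]:
                continue
            seen[start] = True
            comp = [start]
            queue = deque([start])
            while queue:
                u = queue.popleft()
                for v in self._adj[u]:
                    if not seen[v]:
                        seen[v] = True
                        comp.append(v)
                        queue.append(v)
            comps.append(sorted(comp))
        return comps

    def subgraph(self, indices: Sequence[int]) -> "WeightedGraph":
        keep = set(indices)
        sub = WeightedGraph(self._labels[i] for i in sorted(keep))
        for iu in sorted(keep):
            for iv, w in self._adj[iu].items():
                if iv in keep and iu < iv:
                    sub.add_edge(self._labels[iu], self._labels[iv], w)
        return sub

    def __repr__(self) -> str:  # pragma: no cover
        return f"WeightedGraph(n={self.n_vertices}, m={self.n_edges})"


def stationary_distribution(graph: WeightedGraph) -> np.ndarray:
    """Random-walk stationary distribution ``p_v = d_v / vol``.

    Raises :class:`DegenerateGraphError` on a graph with no edges.
    """
    deg = graph.degrees()
    vol = deg.sum()
    if vol <= 0:
        raise DegenerateGraphError("degenerate graph: volume is zero (no edges)")
    return deg / vol


def _entropy_of_positive(deg: np.ndarray, vol: float) -> float:
    p = deg[deg > 0] / vol
    return float(-(p * np.log2(p)).sum())


def one_dim_entropy(graph: WeightedGraph) -> float:
    """One-dimensional structural entropy in bits.

    Disconnected graphs are scored as the volume-weighted average of the
    entropies of their connected components; components without edges
    (isolated vertices) contribute 0.
    """
    deg = graph.degrees()
    vol = float(deg.sum())
    if vol <= 0:
        return 0.0
    total = 0.0
    for comp in graph.connected_components():
        comp_deg = deg[comp]
        comp_vol = float(comp_deg.sum())
        if comp_vol <= 0:
            continue
        h_comp = _entropy_of_positive(comp_deg, comp_vol)
        total += (comp_vol / vol) * h_comp
    return total


# -- edge-list I/O --------------------------------------------------------


def read_edge_list(path, *, delimiter: str = "\t") -> WeightedGraph:
    """Read a three-column ``source<TAB>target<TAB>weight`` edge list.

    A header line is tolerated (detected by a non-numeric third field on the
    first row).  Both ``u v w`` and the redundant symmetric form ``u v w`` +
    ``v u w`` are accepted; a repeated pair with a conflicting weight is an
    error.
    """
    graph = WeightedGraph()
    pending: dict[tuple[str, str], float] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split(delimiter)
            if len(parts) != 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 columns, got {len(parts)}")
            u, v, w_str = (p.strip() for p in parts)
            try:
                w = float(w_str)
            except ValueError:
                if lineno == 1:
                    continue  # header
                raise ValueError(f"{path}: line {lineno}: bad weight {w_str!r}") from None
            key = (u, v) if u <= v else (v, u)
            if key in pending:
                if abs(pending[key] - w) > 1e-12:
                    raise ValueError(
                        f"{path}: line {lineno}: conflicting weight for pair ({u}, {v})"
                    )
                continue
            pending[key] = w
            graph.add_edge(u, v, w)
    return graph


def write_edge_list(graph: WeightedGraph, path, *, delimiter: str = "\t") -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        fh.write(delimiter.join(["source", "target", "weight"]) + "\n")
        for u, v, w in graph.edges():
            fh.write(f"{u}{delimiter}{v}{delimiter}{w:.10g}\n")
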