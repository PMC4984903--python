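"""Greedy minimisation of K-dimensional structural entropy.

Two local operators drive the search, both acting on a pair of sibling
nodes ``alpha`` (left) and ``beta`` (right) of a partitioning tree:

* *merge* — replace the two siblings by a single node holding the union of
  their vertex sets; the children of both (or the siblings themselves, when
  they are leaves) become the children of the new node, concatenated in
  order.  Members of the union are no longer separated and may re-group.
* *combine* — insert a new parent above the two siblings, keeping both as
  intact sub-structures.

Each operator's entropy change ("delta", positive = improvement) depends
only on the volumes and cut weights of the affected nodes and their
children, so it is locally computable; :func:`delta_merge` and
:func:`delta_combine` return exactly ``entropy_before - entropy_after``.

:func:`minimize_entropy` starts from the tree whose root directly covers
singleton leaves and alternates phases: exhaust strictly-improving merges,
apply the single best strictly-improving combine, repeat; it stops when
neither operator improves, then pads the tree to uniform height ``K``.
Ties between candidate pairs are broken toward the first pair in
depth-first parent order and sibling index order, so runs are deterministic
given the input vertex order.

During the greedy run, merge candidates are restricted to depth-1 sibling
pairs (the top-level modules); deeper structure is built exclusively by
the combining operator, which keeps both operands intact.  Unrestricted
deep merges let tiny positive-delta clumps absorb the height budget and
block module-level assembly entirely (e.g. a planted 2-module x
2-submodule graph then surfaces the four submodules at level 1); the
restriction recovers planted two-level structure reliably.  The standalone
operator functions below remain valid for any sibling pair.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .graph import WeightedGraph
from .tree import (
    Partition,
    PartitioningTree,
    TreeNode,
    pad_to_height,
    partition_entropy,
)

__all__ = [
    "apply_merge",
    "apply_combine",
    "delta_merge",
    "delta_combine",
    "minimize_entropy",
    "brute_force_min_partition",
    "TraceStep",
]


@dataclass
class TraceStep:
    step: int
    operator: str  # "merge" | "combine"
    delta: float
    entropy: float  # entropy after the step


# ---------------------------------------------------------------------------
# Plain-tree operators (reference path, used by tests and small inputs)
# ---------------------------------------------------------------------------


def _find_parent(root: TreeNode, target: TreeNode) -> TreeNode | None:
    for child in root.children:
        if child is target:
            return root
        if not child.is_leaf:
            found = _find_parent(child, target)
            if found is not None:
                return found
    return None


def _sibling_context(tree: PartitioningTree, alpha: TreeNode, beta: TreeNode):
    parent = _find_parent(tree.root, alpha)
    if parent is None or _find_parent(tree.root, beta) is not parent:
        raise ValueError("alpha and beta must be siblings in the tree")
    ia = parent.children.index(alpha)
    ib = parent.children.index(beta)
    if ia >= ib:
        raise ValueError("alpha must precede beta in sibling order")
    return parent, ia, ib


def _node_depth(root: TreeNode, target: TreeNode, depth: int = 0) -> int | None:
    if root is target:
        return depth
    for child in root.children:
        found = _node_depth(child, target, depth + 1)
        if found is not None:
            return found
    return None


def _set_stats(graph: WeightedGraph, labels: list[str]) -> tuple[float, float]:
    idx = {graph.index_of(v) for v in labels}
    vol = 0.0
    cut = 0.0
    for iu in idx:
        for iv, w in graph.neighbors(iu).items():
            vol += w
            if iv not in idx:
                cut += w
    return vol, cut


def _cross_weight(graph: WeightedGraph, a: list[str], b: list[str]) -> float:
    small, large = (a, b) if len(a) <= len(b) else (b, a)
    large_idx = {graph.index_of(v) for v in large}
    total = 0.0
    for v in small:
        for iv, w in graph.neighbors(graph.index_of(v)).items():
            if iv in large_idx:
                total += w
    return total


def _term(g: float, v: float, v_parent: float, vol: float) -> float:
    if g <= 0 or v <= 0:
        return 0.0
    return (g / vol) * math.log2(v_parent / v)


def apply_merge(tree: PartitioningTree, alpha: TreeNode, beta: TreeNode) -> PartitioningTree:
    """Merge sibling nodes in place; returns the (mutated) tree.

    The node replacing ``alpha`` adopts the children of both siblings in
    order; a sibling that is itself a leaf becomes a child of the merged
    node, so merging two singleton leaves yields one module node with two
    singleton leaf children.
    """
    parent, ia, ib = _sibling_context(tree, alpha, beta)
    new_children = (alpha.children if not alpha.is_leaf else [alpha]) + (
        beta.children if not beta.is_leaf else [beta]
    )
    merged = TreeNode(list(new_children))
    parent.children[ia] = merged
    del parent.children[ib]
    return tree


def apply_combine(
    tree: PartitioningTree, alpha: TreeNode, beta: TreeNode, K: int | None = None
) -> PartitioningTree:
    """Insert a new parent over two siblings in place; returns the tree.

    When ``K`` is given, rejects the operation if any leaf below the new
    node would end deeper than ``K``.
    """
    parent, ia, ib = _sibling_context(tree, alpha, beta)
    if K is not None:
        depth = _node_depth(tree.root, parent)
        assert depth is not None
        if depth + 2 + max(alpha.height(), beta.height()) > K:
            raise ValueError("combine would exceed height K")
    xi = TreeNode([alpha, beta])
    parent.children[ia] = xi
    del parent.children[ib]
    return tree


def delta_merge(
    graph: WeightedGraph, tree: PartitioningTree, alpha: TreeNode, beta: TreeNode
) -> float:
    """Entropy decrease of merging two siblings, from local quantities only."""
    parent, _, _ = _sibling_context(tree, alpha, beta)
    vol = graph.volume
    a_labels, b_labels = alpha.vertex_list(), beta.vertex_list()
    va, ga = _set_stats(graph, a_labels)
    vb, gb = _set_stats(graph, b_labels)
    vp = vol if parent is tree.root else _set_stats(graph, parent.vertex_list())[0]
    w_ab = _cross_weight(graph, a_labels, b_labels)
    vn = va + vb
    gn = ga + gb - 2.0 * w_ab

    def child_terms(node: TreeNode, parent_vol: float) -> float:
        acc = 0.0
        for c in node.children:
            vc, gc = _set_stats(graph, c.vertex_list())
            acc += _term(gc, vc, parent_vol, vol)
        return acc

    before = (
        _term(ga, va, vp, vol)
        + _term(gb, vb, vp, vol)
        + child_terms(alpha, va)
        + child_terms(beta, vb)
    )
    after = _term(gn, vn, vp, vol)
    for node, (v_own, g_own) in ((alpha, (va, ga)), (beta, (vb, gb))):
        if node.is_leaf:
            after += _term(g_own, v_own, vn, vol)
        else:
            after += child_terms(node, vn)
    return before - after


def delta_combine(
    graph: WeightedGraph, tree: PartitioningTree, alpha: TreeNode, beta: TreeNode
) -> float:
    """Entropy decrease of combining two siblings, from local quantities only."""
    parent, _, _ = _sibling_context(tree, alpha, beta)
    vol = graph.volume
    a_labels, b_labels = alpha.vertex_list(), beta.vertex_list()
    va, ga = _set_stats(graph, a_labels)
    vb, gb = _set_stats(graph, b_labels)
    vp = vol if parent is tree.root else _set_stats(graph, parent.vertex_list())[0]
    w_ab = _cross_weight(graph, a_labels, b_labels)
    vn = va + vb
    gn = ga + gb - 2.0 * w_ab
    before = _term(ga, va, vp, vol) + _term(gb, vb, vp, vol)
    after = _term(gn, vn, vp, vol) + _term(ga, va, vn, vol) + _term(gb, vb, vn, vol)
    return before - after


# ---------------------------------------------------------------------------
# Fast greedy minimiser
# ---------------------------------------------------------------------------


class _MNode:
    """Minimiser-internal tree node with cached volume/cut statistics."""

    __slots__ = ("children", "vertex", "vertices", "vol", "cut", "s_cut", "t_cut", "sheight")

    def __init__(self):
        self.children: list[_MNode] = []
        self.vertex: int | None = None
        self.vertices: set[int] = set()
        self.vol = 0.0
        self.cut = 0.0
        self.s_cut = 0.0  # sum of children's cuts
        self.t_cut = 0.0  # sum of children's cut * log2(child volume)
        self.sheight = 0

    @property
    def is_leaf(self) -> bool:
        return self.vertex is not None

    def refresh_child_sums(self) -> None:
        self.s_cut = sum(c.cut for c in self.children)
        self.t_cut = sum(c.cut * math.log2(c.vol) for c in self.children if c.vol > 0)


@dataclass
class _Candidate:
    delta: float
    parent: "_MNode"
    ia: int
    ib: int
    w_ab: float


class _Minimizer:
    def __init__(self, graph: WeightedGraph, K: int):
        self.graph = graph
        self.K = K
        self.vol = graph.volume
        deg = graph.degrees()
        self.root = _MNode()
        self.root.vertices = set(range(graph.n_vertices))
        self.root.vol = self.vol
        self.root.sheight = 1
        for i in range(graph.n_vertices):
            leaf = _MNode()
            leaf.vertex = i
            leaf.vertices = {i}
            leaf.vol = float(deg[i])
            leaf.cut = float(deg[i])
            self.root.children.append(leaf)
        self.root.refresh_child_sums()
        self.entropy = sum(
            _term(c.cut, c.vol, self.vol, self.vol) for c in self.root.children
        )
        self.trace: list[TraceStep] = []

    # -- candidate enumeration --------------------------------------------

    def _internal_nodes(self):
        """Internal nodes with >= 2 children, in depth-first order with depth."""
        stack = [(self.root, 0)]
        while stack:
            node, depth = stack.pop()
            if not node.is_leaf:
                yield node, depth
                for child in reversed(node.children):
                    if not child.is_leaf:
                        stack.append((child, depth + 1))

    def _sibling_links(self, parent: _MNode) -> dict[tuple[int, int], float]:
        """Total edge weight between every connected pair of children."""
        owner: dict[int, int] = {}
        for pos, child in enumerate(parent.children):
            for v in child.vertices:
                owner[v] = pos
        links: dict[tuple[int, int], float] = {}
        for v, pos in owner.items():
            for u, w in self.graph.neighbors(v).items():
                qos = owner.get(u)
                if qos is not None and qos != pos:
                    key = (pos, qos) if pos < qos else (qos, pos)
                    links[key] = links.get(key, 0.0) + w
        return {k: w / 2.0 for k, w in links.items()}

    def _child_term_sums(self, node: _MNode) -> tuple[float, float]:
        """(S, T) used in the merged-node children contribution.

        For a leaf sibling the node itself becomes a child of the merged
        node, so its own (cut, cut*log2(vol)) pair stands in for the sums.
        """
        if node.is_leaf:
            t = node.cut * math.log2(node.vol) if node.vol > 0 else 0.0
            return node.cut, t
        return node.s_cut, node.t_cut

    def _delta_merge(self, parent: _MNode, a: _MNode, b: _MNode, w_ab: float) -> float:
        vol = self.vol
        vp = parent.vol
        vn = a.vol + b.vol
        gn = a.cut + b.cut - 2.0 * w_ab
        before = _term(a.cut, a.vol, vp, vol) + _term(b.cut, b.vol, vp, vol)
        after = _term(gn, vn, vp, vol)
        if vn > 0:
            lg_vn = math.log2(vn)
            for node in (a, b):
                s, t = self._child_term_sums(node)
                after += (s * lg_vn - t) / vol
                if not node.is_leaf and node.vol > 0:
                    before += (node.s_cut * math.log2(node.vol) - node.t_cut) / vol
        return before - after

    def _delta_combine(self, parent: _MNode, a: _MNode, b: _MNode, w_ab: float) -> float:
        vol = self.vol
        vp = parent.vol
        vn = a.vol + b.vol
        gn = a.cut + b.cut - 2.0 * w_ab
        before = _term(a.cut, a.vol, vp, vol) + _term(b.cut, b.vol, vp, vol)
        after = (
            _term(gn, vn, vp, vol)
            + _term(a.cut, a.vol, vn, vol)
            + _term(b.cut, b.vol, vn, vol)
        )
        return before - after

    def _merge_depth_ok(self, depth_parent: int, a: _MNode, b: _MNode) -> bool:
        sub = max(
            a.sheight - 1 if not a.is_leaf else 0,
            b.sheight - 1 if not b.is_leaf else 0,
        )
        return depth_parent + 2 + sub <= self.K

    def _combine_depth_ok(self, depth_parent: int, a: _MNode, b: _MNode) -> bool:
        return depth_parent + 2 + max(a.sheight, b.sheight) <= self.K

    def _best_merge(self, include_disconnected: bool = False) -> _Candidate | None:
        # Greedy merge candidates are restricted to depth-1 siblings
        # (children of the root): modules grow flat at the top while the
        # combining operator alone builds the inner levels.  Allowing
        # deeper merges lets micro-clumps consume the height budget before
        # any module-scale combine can fire (see decision notes).
        best: _Candidate | None = None
        parent = self.root
        if len(parent.children) < 2:
            return None
        links = self._sibling_links(parent)
        if include_disconnected:
            pairs = [
                (i, j)
                for i in range(len(parent.children))
                for j in range(i + 1, len(parent.children))
            ]
        else:
            pairs = sorted(links)
        for i, j in pairs:
            a, b = parent.children[i], parent.children[j]
            if not self._merge_depth_ok(0, a, b):
                continue
            w_ab = links.get((i, j), 0.0)
            delta = self._delta_merge(parent, a, b, w_ab)
            if delta > 0 and (best is None or delta > best.delta):
                best = _Candidate(delta, parent, i, j, w_ab)
        return best

    def _best_combine(self) -> _Candidate | None:
        best: _Candidate | None = None
        for parent, depth in self._internal_nodes():
            if len(parent.children) < 2:
                continue
            links = self._sibling_links(parent)
            for i, j in sorted(links):
                a, b = parent.children[i], parent.children[j]
                if not self._combine_depth_ok(depth, a, b):
                    continue
                w_ab = links[(i, j)]
                delta = self._delta_combine(parent, a, b, w_ab)
                if delta > 0 and (best is None or delta > best.delta):
                    best = _Candidate(delta, parent, i, j, w_ab)
        return best

    # -- operator application ---------------------------------------------

    def _apply_merge(self, cand: _Candidate) -> None:
        parent, a, b = cand.parent, cand.parent.children[cand.ia], cand.parent.children[cand.ib]
        merged = _MNode()
        merged.children = (a.children if not a.is_leaf else [a]) + (
            b.children if not b.is_leaf else [b]
        )
        merged.vertices = a.vertices | b.vertices
        merged.vol = a.vol + b.vol
        merged.cut = a.cut + b.cut - 2.0 * cand.w_ab
        merged.sheight = 1 + max(c.sheight for c in merged.children)
        merged.refresh_child_sums()
        parent.children[cand.ia] = merged
        del parent.children[cand.ib]
        parent.refresh_child_sums()
        self._refresh_heights()

    def _apply_combine(self, cand: _Candidate) -> None:
        parent, a, b = cand.parent, cand.parent.children[cand.ia], cand.parent.children[cand.ib]
        xi = _MNode()
        xi.children = [a, b]
        xi.vertices = a.vertices | b.vertices
        xi.vol = a.vol + b.vol
        xi.cut = a.cut + b.cut - 2.0 * cand.w_ab
        xi.sheight = 1 + max(a.sheight, b.sheight)
        xi.refresh_child_sums()
        parent.children[cand.ia] = xi
        del parent.children[cand.ib]
        parent.refresh_child_sums()
        self._refresh_heights()

    def _refresh_heights(self) -> None:
        def walk(node: _MNode) -> int:
            if node.is_leaf:
                node.sheight = 0
            else:
                node.sheight = 1 + max(walk(c) for c in node.children)
            return node.sheight

        walk(self.root)

    # -- main loop ----------------------------------------------------------

    def run(self) -> None:
        step = 0
        max_steps = 4 * self.graph.n_vertices * self.graph.n_vertices + 16
        while step < max_steps:
            cand = self._best_merge()
            if cand is None:
                cand = self._best_merge(include_disconnected=True)
            if cand is not None:
                step += 1
                self._apply_merge(cand)
                self.entropy -= cand.delta
                self.trace.append(TraceStep(step, "merge", cand.delta, self.entropy))
                continue
            cand = self._best_combine()
            if cand is None:
                break
            step += 1
            self._apply_combine(cand)
            self.entropy -= cand.delta
            self.trace.append(TraceStep(step, "combine", cand.delta, self.entropy))
        else:  # pragma: no cover - safeguard
            warnings.warn("minimizer step cap reached; returning current tree")

    def to_tree(self) -> PartitioningTree:
        labels = self.graph.vertex_labels

        def convert(node: _MNode) -> TreeNode:
            if node.is_leaf:
                return TreeNode(vertex=labels[node.vertex])
            return TreeNode([convert(c) for c in node.children])

        return PartitioningTree(convert(self.root))


def minimize_entropy(
    graph: WeightedGraph,
    K: int = 2,
    *,
    trace_out: list[TraceStep] | None = None,
) -> PartitioningTree:
    """Greedy height-``K`` structural-entropy minimisation.

    Returns a partitioning tree padded to uniform height ``K``; level-1 sets
    are the modules and (for ``K >= 3``) level-2 sets the submodules.  When
    ``trace_out`` is given, one :class:`TraceStep` per applied operator is
    appended to it.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if graph.n_vertices == 0:
        raise ValueError("empty graph")
    if graph.volume <= 0:
        warnings.warn("degenerate graph (no edges): returning the trivial single-module tree")
        module = TreeNode([TreeNode(vertex=v) for v in graph.vertex_labels])
        return pad_to_height(PartitioningTree(TreeNode([module])), K)
    minimizer = _Minimizer(graph, K)
    minimizer.run()
    if trace_out is not None:
        trace_out.extend(minimizer.trace)
    return pad_to_height(minimizer.to_tree(), K)


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------


def _set_partitions(items: list[str]):
    """All set partitions, in restricted-growth-string lexicographic order."""
    n = len(items)
    if n == 0:
        return
    rgs = [0] * n

    def rec(i: int, maxval: int):
        if i == n:
            nblocks = maxval + 1
            blocks: list[list[str]] = [[] for _ in range(nblocks)]
            for pos, b in enumerate(rgs):
                blocks[b].append(items[pos])
            yield blocks
            return
        for b in range(maxval + 2):
            rgs[i] = b
            yield from rec(i + 1, max(maxval, b))

    rgs[0] = 0
    yield from rec(1, 0)


def brute_force_min_partition(
    graph: WeightedGraph, *, max_n: int = 10
) -> tuple[Partition, float]:
    """Exact minimum of :func:`partition_entropy` over all set partitions.

    Exponential (Bell-number) enumeration; refuses graphs larger than
    ``max_n`` vertices.  Ties go to the first partition in enumeration
    order.
    """
    if graph.n_vertices > max_n:
        raise ValueError(f"brute force limited to n <= {max_n} vertices")
    if graph.volume <= 0:
        raise ValueError("graph volume is zero")
    best_partition: Partition | None = None
    best_entropy = math.inf
    for blocks in _set_partitions(graph.vertex_labels):
        partition = Partition(blocks)
        h = partition_entropy(graph, partition)
        if h < best_entropy - 1e-15:
            best_entropy = h
            best_partition = partition
    assert best_partition is not None
    return best_partition, best_entropy
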