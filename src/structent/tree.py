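"""Partitioning trees and structural entropy of partitions and trees.

A partitioning tree of a graph is a rooted ordered tree whose root holds the
full vertex set, whose leaves hold single vertices, and in which every node's
vertex set is the disjoint union of its children's.  After padding to uniform
height ``K``, the nodes at each depth form a partition of the vertex set; the
depth-1 sets are the *modules* and the depth-2 sets the *submodules*.

Two equivalent entropy scores are implemented:

* :func:`partition_entropy` — the explicit two-level form over a flat
  partition ``X_1..X_L``:

      sum_j (Vol_j/vol) * H(d_i / Vol_j : i in X_j)
      + sum_j (g_j/vol) * log2(vol / Vol_j)

* :func:`tree_entropy` — the general form over any partitioning tree:

      sum_{alpha != root} (g_alpha/vol) * log2(V_parent(alpha) / V_alpha)

where ``V`` is vertex-set volume and ``g`` cut weight.  The displayed
equations in the source text are not reproduced there; these canonical forms
are reconstructed from the printed symbol definitions, and their algebraic
identity on height-2 trees is enforced by the test suite.
"""

from __future__ import annotations

import json
import math
from typing import Iterable, Iterator, Sequence

from .graph import WeightedGraph

__all__ = [
    "TreeNode",
    "PartitioningTree",
    "Partition",
    "TreeValidationError",
    "partition_entropy",
    "tree_entropy",
    "level_partition",
    "pad_to_height",
    "naturality_ratio",
]


class TreeValidationError(ValueError):
    """A partitioning tree violates coverage/disjointness; names the node."""


class TreeNode:
    """Ordered tree node; a leaf holds exactly one graph vertex label."""

    __slots__ = ("children", "vertex")

    def __init__(self, children: list["TreeNode"] | None = None, vertex: str | None = None):
        self.children: list[TreeNode] = children if children is not None else []
        self.vertex = vertex

    @property
    def is_leaf(self) -> bool:
        return self.vertex is not None

    def leaves(self) -> Iterator["TreeNode"]:
        if self.is_leaf:
            yield self
        else:
            for c in self.children:
                yield from c.leaves()

    def vertex_list(self) -> list[str]:
        """Vertices below this node in leaf (left-to-right) order."""
        return [leaf.vertex for leaf in self.leaves()]  # type: ignore[misc]

    def height(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(c.height() for c in self.children)

    def min_leaf_depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + min(c.min_leaf_depth() for c in self.children)


class PartitioningTree:
    """Rooted ordered tree over the vertices of a graph."""

    def __init__(self, root: TreeNode):
        self.root = root

    # -- constructors ------------------------------------------------------

    @classmethod
    def singleton_tree(cls, labels: Sequence[str]) -> "PartitioningTree":
        """Root directly over one singleton leaf per vertex."""
        return cls(TreeNode([TreeNode(vertex=v) for v in labels]))

    @classmethod
    def from_partition(cls, partition: "Partition") -> "PartitioningTree":
        """Height-2 tree: root -> one node per block -> singleton leaves."""
        modules = [
            TreeNode([TreeNode(vertex=v) for v in block]) for block in partition.blocks
        ]
        return cls(TreeNode(modules))

    # -- structure ---------------------------------------------------------

    @property
    def height(self) -> int:
        return self.root.height()

    def is_uniform_height(self) -> bool:
        return self.root.height() == self.root.min_leaf_depth()

    def vertex_list(self) -> list[str]:
        return self.root.vertex_list()

    def validate(self, graph: WeightedGraph) -> None:
        labels = set(graph.vertex_labels)
        seen: set[str] = set()
        self._validate_node(self.root, "root", labels, seen)
        missing = labels - seen
        if missing:
            raise TreeValidationError(f"root: vertices not covered: {sorted(missing)}")

    def _validate_node(self, node: TreeNode, path: str, labels: set, seen: set) -> None:
        if node.is_leaf:
            if node.children:
                raise TreeValidationError(f"{path}: leaf has children")
            if node.vertex not in labels:
                raise TreeValidationError(f"{path}: unknown vertex {node.vertex!r}")
            if node.vertex in seen:
                raise TreeValidationError(f"{path}: vertex {node.vertex!r} appears twice")
            seen.add(node.vertex)
            return
        if not node.children:
            raise TreeValidationError(f"{path}: internal node has no children")
        for i, child in enumerate(node.children, start=1):
            self._validate_node(child, f"{path}.{i}" if path != "root" else str(i), labels, seen)

    # -- labelling and serialisation --------------------------------------

    def node_paths(self) -> Iterator[tuple[str, TreeNode]]:
        """Yield (dotted 1-based path label, node); root has label 'root'."""

        def walk(node: TreeNode, path: str):
            yield path, node
            for i, child in enumerate(node.children, start=1):
                sub = f"{path}.{i}" if path != "root" else str(i)
                yield from walk(child, sub)

        yield from walk(self.root, "root")

    def to_dict(self) -> dict:
        def encode(node: TreeNode, path: str) -> dict:
            if node.is_leaf:
                return {"label": path, "vertex": node.vertex}
            return {
                "label": path,
                "children": [
                    encode(c, f"{path}.{i}" if path != "root" else str(i))
                    for i, c in enumerate(node.children, start=1)
                ],
            }

        return encode(self.root, "root")

    @classmethod
    def from_dict(cls, data: dict) -> "PartitioningTree":
        def decode(obj: dict) -> TreeNode:
            if "vertex" in obj:
                return TreeNode(vertex=obj["vertex"])
            return TreeNode([decode(c) for c in obj["children"]])

        return cls(decode(data))

    def to_json(self, path) -> None:
        with open(path, "wt", encoding="utf-8", newline="\n") as fh:
            json.dump(self.to_dict(), fh, indent=1, ensure_ascii=False)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "PartitioningTree":
        with open(path, "rt", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def copy(self) -> "PartitioningTree":
        def dup(node: TreeNode) -> TreeNode:
            if node.is_leaf:
                return TreeNode(vertex=node.vertex)
            return TreeNode([dup(c) for c in node.children])

        return PartitioningTree(dup(self.root))


class Partition:
    """Ordered partition of a vertex set into non-empty blocks."""

    def __init__(self, blocks: Iterable[Sequence[str]]):
        self.blocks: list[list[str]] = [list(b) for b in blocks]
        if not self.blocks:
            raise ValueError("partition must have at least one block")
        seen: set[str] = set()
        for i, block in enumerate(self.blocks):
            if not block:
                raise ValueError(f"block {i + 1} is empty")
            for v in block:
                if v in seen:
                    raise ValueError(f"vertex {v!r} appears in more than one block")
                seen.add(v)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def universe(self) -> set:
        return {v for block in self.blocks for v in block}

    def membership(self) -> dict[str, int]:
        return {v: j for j, block in enumerate(self.blocks) for v in block}

    def __eq__(self, other) -> bool:
        return isinstance(other, Partition) and self.blocks == other.blocks

    def __repr__(self) -> str:  # pragma: no cover
        return f"Partition({self.blocks!r})"


# -- entropy -------------------------------------------------------------


def _block_stats(graph: WeightedGraph, indices: set[int]) -> tuple[float, float]:
    """(volume, cut weight) of a vertex-index set."""
    vol = 0.0
    cut = 0.0
    for iu in indices:
        for iv, w in graph.neighbors(iu).items():
            vol += w
            if iv not in indices:
                cut += w
    return vol, cut


def partition_entropy(graph: WeightedGraph, partition: Partition) -> float:
    """Structural entropy of ``graph`` under a flat partition, in bits."""
    if partition.universe() != set(graph.vertex_labels):
        raise ValueError("partition does not cover the graph's vertex set")
    vol = graph.volume
    if vol <= 0:
        raise ValueError("graph volume is zero")
    deg = graph.degrees()
    total = 0.0
    for block in partition.blocks:
        idx = {graph.index_of(v) for v in block}
        block_vol, cut = _block_stats(graph, idx)
        if block_vol <= 0:
            continue  # isolated-vertex block contributes nothing
        # within-block positioning term
        for i in idx:
            d = deg[i]
            if d > 0:
                total -= (d / vol) * math.log2(d / block_vol)
        # cut term
        if cut > 0:
            total += (cut / vol) * math.log2(vol / block_vol)
    return total


def tree_entropy(graph: WeightedGraph, tree: PartitioningTree) -> float:
    """Structural entropy of ``graph`` under a partitioning tree, in bits."""
    tree.validate(graph)
    vol = graph.volume
    if vol <= 0:
        raise ValueError("graph volume is zero")

    def node_term(node: TreeNode) -> tuple[float, float]:
        """Return (volume of node's set, entropy of node's subtree)."""
        idx = {graph.index_of(v) for v in node.vertex_list()}
        node_vol, _ = _block_stats(graph, idx)
        acc = 0.0
        for child in node.children:
            cidx = {graph.index_of(v) for v in child.vertex_list()}
            child_vol, child_cut = _block_stats(graph, cidx)
            if child_vol > 0 and child_cut > 0:
                acc += (child_cut / vol) * math.log2(node_vol / child_vol)
            _, sub = node_term(child)
            acc += sub
        return node_vol, acc

    _, total = node_term(tree.root)
    return total


def level_partition(tree: PartitioningTree, level: int) -> Partition:
    """Partition formed by the tree nodes at the given depth (root = 0)."""
    if level < 1:
        raise ValueError("level must be >= 1")
    height = tree.height
    if level > height:
        raise ValueError(f"level {level} exceeds tree height {height}")
    if not tree.is_uniform_height():
        raise ValueError("tree must be padded to uniform height first")

    blocks: list[list[str]] = []

    def walk(node: TreeNode, depth: int) -> None:
        if depth == level:
            blocks.append(node.vertex_list())
            return
        for c in node.children:
            walk(c, depth + 1)

    walk(tree.root, 0)
    return Partition(blocks)


def pad_to_height(tree: PartitioningTree, K: int) -> PartitioningTree:
    """Insert unary pass-through nodes so every leaf sits at depth ``K``.

    The pass-through for a uniformly shallow subtree is inserted as high as
    possible, directly above the subtree root, so that a flat block of
    vertices stays together as one set on intermediate levels.  Entropy is
    unchanged: an inserted node has the same volume as its parent, so its
    log-ratio term is zero.  Modifies the tree in place and returns it.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    height = tree.height
    if height > K:
        raise ValueError(f"tree height {height} exceeds requested height {K}")

    def pad(node: TreeNode, depth: int) -> None:
        for i, child in enumerate(node.children):
            need = K - depth - 1 - child.height()
            if need > 0:
                wrapped = child
                for _ in range(need):
                    wrapped = TreeNode([wrapped])
                node.children[i] = wrapped
                pad(child, depth + 1 + need)
            else:
                pad(child, depth + 1)

    pad(tree.root, 0)
    return tree


def naturality_ratio(graph: WeightedGraph, tree: PartitioningTree) -> float:
    """Diagnostic ratio tree_entropy / one_dim_entropy (no threshold claim)."""
    from .graph import one_dim_entropy

    h1 = one_dim_entropy(graph)
    if h1 <= 0:
        return float("nan")
    return tree_entropy(graph, tree) / h1
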