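"""Gene-map construction and partition-similarity scoring.

Each gene's expression vector is coded to mean 0 with values in [-1, 1]
(mean-centre, then scale by the maximum absolute deviation).  Given sample
groups X_1..X_L (modules or submodules), every gene is assigned to the
group with the highest mean coded expression; block B_j collects the genes
assigned to X_j, sorted by decreasing defining-group mean.  Reordering rows
by B_1..B_L and columns by X_1..X_L yields a block-patterned matrix in
which each group is characterised by its gene block.

Similarity of a found module partition to a ground-truth typing is scored
per true type as the best set overlap against any found module (Jaccard by
default; an asymmetric recall variant |X&Y|/|Y| is available), plus a
size-weighted average.  The source text's displayed similarity formula is
not reproduced there; Jaccard is the documented reconstruction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tree import Partition, PartitioningTree, level_partition

__all__ = [
    "normalise_gene",
    "normalise_matrix",
    "group_mean_expression",
    "assign_genes",
    "gene_map",
    "set_similarity",
    "partition_similarity",
    "GeneMap",
    "SimilarityTable",
]


def normalise_gene(values) -> np.ndarray:
    """Code one gene's per-sample vector to mean 0 and range within [-1, 1].

    ``b = a - mean(a); c = b / max|b|``; a constant profile codes to all
    zeros.
    """
    a = np.asarray(values, dtype=float)
    b = a - a.mean()
    b -= b.mean()  # second pass kills cancellation error from large offsets
    peak = np.abs(b).max()
    if peak == 0:
        return np.zeros_like(b)
    return b / peak


def normalise_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`normalise_gene` to every row (gene) of the matrix."""
    values = expr.to_numpy(dtype=float)
    centred = values - values.mean(axis=1, keepdims=True)
    centred -= centred.mean(axis=1, keepdims=True)
    peaks = np.abs(centred).max(axis=1, keepdims=True)
    peaks[peaks == 0] = 1.0
    return pd.DataFrame(centred / peaks, index=expr.index, columns=expr.columns)


def group_mean_expression(norm: pd.DataFrame, partition: Partition) -> pd.DataFrame:
    """Mean coded expression of every gene in every sample group.

    Columns are the 1-based group indices of the partition, in order.
    """
    missing = partition.universe() - set(map(str, norm.columns))
    if missing:
        raise ValueError(f"partition samples missing from matrix: {sorted(missing)}")
    cols = {}
    for j, block in enumerate(partition.blocks, start=1):
        if not block:
            raise ValueError(f"group {j} is empty")
        cols[j] = norm[block].mean(axis=1)
    return pd.DataFrame(cols, index=norm.index)


def assign_genes(means: pd.DataFrame) -> list[list[str]]:
    """Partition genes into blocks B_1..B_L by arg-max group mean.

    Ties go to the lowest group index.  Within each block genes are sorted
    by decreasing defining-group mean (stable, so equal means keep input
    order).
    """
    arr = means.to_numpy(dtype=float)
    winners = np.argmax(arr, axis=1)  # first maximum wins ties
    blocks: list[list[str]] = []
    genes = np.asarray(means.index)
    for j in range(means.shape[1]):
        in_block = np.flatnonzero(winners == j)
        order = in_block[np.argsort(-arr[in_block, j], kind="stable")]
        blocks.append([str(g) for g in genes[order]])
    return blocks


@dataclass
class GeneMap:
    """Reordered coded matrix with gene-block / sample-group boundaries."""

    matrix: pd.DataFrame  # rows B_1..B_L concatenated, columns X_1..X_L
    gene_blocks: list[list[str]]
    sample_groups: list[list[str]]
    group_labels: list[str]
    row_boundaries: list[int]  # cumulative row counts after each block
    col_boundaries: list[int]

    def assignments(self) -> pd.DataFrame:
        """Long-form (gene, block label, defining-group mean) table."""
        rows = []
        for label, block, group in zip(self.group_labels, self.gene_blocks, self.sample_groups):
            for gene in block:
                rows.append(
                    {
                        "gene_id": gene,
                        "block": label,
                        "defining_group_mean": float(self.matrix.loc[gene, group].mean()),
                    }
                )
        return pd.DataFrame(rows, columns=["gene_id", "block", "defining_group_mean"])


def _groups_from_tree(tree: PartitioningTree, level: int) -> tuple[list[list[str]], list[str]]:
    partition = level_partition(tree, level)
    labels = []
    for path, node in tree.node_paths():
        if path != "root" and path.count(".") == level - 1:
            labels.append(path)
    return partition.blocks, labels


def gene_map(
    norm: pd.DataFrame,
    groups: Partition | PartitioningTree,
    *,
    level: int = 1,
) -> GeneMap:
    """Build the reordered gene x sample map for a partition or tree level.

    For a tree, groups are the vertex sets at the requested depth (level 1:
    modules; level 2: submodules ordered by parent module then sibling
    order).  Samples inside a group keep the matrix's column order.
    """
    if isinstance(groups, PartitioningTree):
        blocks, labels = _groups_from_tree(groups, level)
    else:
        blocks = groups.blocks
        labels = [str(j) for j in range(1, len(blocks) + 1)]
    col_order = {str(c): i for i, c in enumerate(norm.columns)}
    sample_groups = [sorted(block, key=lambda s: col_order[s]) for block in blocks]

    partition = Partition(sample_groups)
    means = group_mean_expression(norm, partition)
    gene_blocks = assign_genes(means)

    row_order = [g for block in gene_blocks for g in block]
    col_order_flat = [s for group in sample_groups for s in group]
    matrix = norm.loc[row_order, col_order_flat]

    row_bounds, acc = [], 0
    for block in gene_blocks:
        acc += len(block)
        row_bounds.append(acc)
    col_bounds, acc = [], 0
    for group in sample_groups:
        acc += len(group)
        col_bounds.append(acc)
    return GeneMap(matrix, gene_blocks, sample_groups, labels, row_bounds, col_bounds)


def set_similarity(x: set, y: set, *, metric: str = "jaccard") -> float:
    """Overlap score of two sample sets in [0, 1].

    ``jaccard``: |X & Y| / |X | Y|.  ``recall``: |X & Y| / |Y| (how much of
    the true set Y the found set X captures).  Two empty sets score 0 with
    a warning.
    """
    x, y = set(x), set(y)
    if not x and not y:
        warnings.warn("similarity of two empty sets defined as 0")
        return 0.0
    inter = len(x & y)
    if metric == "jaccard":
        return inter / len(x | y)
    if metric == "recall":
        if not y:
            warnings.warn("similarity to an empty true set defined as 0")
            return 0.0
        return inter / len(y)
    raise ValueError(f"unknown metric {metric!r}")


@dataclass
class SimilarityTable:
    """Best-match similarity of found modules to each true type."""

    true_labels: list[str]
    true_sizes: list[int]
    scores: list[float]
    best_found: list[int]  # 1-based index of the best-matching found module
    weighted_average: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "true_type": self.true_labels,
                "size": self.true_sizes,
                "best_found_module": self.best_found,
                "similarity": self.scores,
            }
        )


def partition_similarity(
    found: Partition,
    truth: Partition,
    *,
    metric: str = "jaccard",
    truth_labels: list[str] | None = None,
) -> SimilarityTable:
    """Score every true type by its best-matching found module.

    The weighted average weights each true type by its share of the sample
    universe.
    """
    fu, tu = found.universe(), truth.universe()
    if fu != tu:
        extra = sorted(fu - tu)
        missing = sorted(tu - fu)
        raise ValueError(
            f"sample universe mismatch: extra in found {extra}, missing from found {missing}"
        )
    n = len(tu)
    labels = truth_labels or [str(j) for j in range(1, truth.n_blocks + 1)]
    scores, best_idx, sizes = [], [], []
    for block in truth.blocks:
        y = set(block)
        best, who = -1.0, 0
        for i, fblock in enumerate(found.blocks, start=1):
            s = set_similarity(set(fblock), y, metric=metric)
            if s > best:
                best, who = s, i
        scores.append(best)
        best_idx.append(who)
        sizes.append(len(y))
    weighted = float(sum(s * sz for s, sz in zip(scores, sizes)) / n)
    return SimilarityTable(labels, sizes, scores, best_idx, weighted)
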