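"""Readers and writers for the plain-text formats used by the pipeline.

Expression matrices: delimited text with gene ids in the first column and
sample ids in the header (TSV by default, CSV by extension), or GCT (two
preamble lines, then Name/Description columns).  Partitions: two-column
``sample_id<TAB>module_path`` tables with 1-based dotted module paths.
All outputs are tab-separated UTF-8 with LF endings.
"""

from __future__ import annotations

import pandas as pd

from .network import EntropyCurve
from .tree import Partition, PartitioningTree

__all__ = [
    "read_expression",
    "write_expression",
    "read_partition_table",
    "write_partition_table",
    "tree_partition_table",
    "read_labels",
    "write_curve",
    "read_curve",
]


def _delimiter_for(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_expression(path, *, impute_missing: bool = False) -> pd.DataFrame:
    """Read a genes x samples matrix from TSV/CSV/GCT.

    Missing values are rejected unless ``impute_missing`` is set, in which
    case they are filled with the gene-wise mean.
    """
    spath = str(path)
    if spath.lower().endswith(".gct"):
        with open(path, "rt", encoding="utf-8") as fh:
            version = fh.readline().strip()
            if not version.startswith("#1."):
                raise ValueError(f"{path}: line 1: not a GCT version header: {version!r}")
            fh.readline()  # dimensions line; trusted but unused
            df = pd.read_csv(fh, sep="\t", index_col=0)
        df = df.drop(columns=[c for c in ("Description",) if c in df.columns])
    else:
        df = pd.read_csv(path, sep=_delimiter_for(path), index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene ids: {dup[:5]}")
    if df.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate sample ids")
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric expression values: {exc}") from None
    if df.isna().any().any():
        if not impute_missing:
            gene = df.index[df.isna().any(axis=1)][0]
            raise ValueError(
                f"{path}: missing values (first offender: gene {gene!r}); "
                "pass impute_missing to fill with gene means"
            )
        means = df.mean(axis=1)
        df = df.apply(lambda row: row.fillna(means[row.name]), axis=1)
    return df


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep=_delimiter_for(path), index_label="gene_id", lineterminator="\n")


def read_partition_table(path) -> Partition:
    """Read ``sample_id<TAB>module_path``; blocks ordered by module path."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns, got {df.shape[1]}")
    sample_col, path_col = df.columns
    blocks: dict[str, list[str]] = {}
    for sid, mpath in zip(df[sample_col], df[path_col]):
        blocks.setdefault(mpath, []).append(sid)

    def path_key(p: str):
        return tuple(int(x) for x in p.split("."))

    return Partition([blocks[p] for p in sorted(blocks, key=path_key)])


def write_partition_table(partition: Partition, path, *, labels=None) -> None:
    labels = labels or [str(j) for j in range(1, partition.n_blocks + 1)]
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        fh.write("sample_id\tmodule_path\n")
        for label, block in zip(labels, partition.blocks):
            for sid in block:
                fh.write(f"{sid}\t{label}\n")


def tree_partition_table(tree: PartitioningTree, level: int) -> tuple[Partition, list[str]]:
    """Level partition of a padded tree plus its dotted module-path labels."""
    from .tree import level_partition

    partition = level_partition(tree, level)
    labels = [
        path
        for path, _node in tree.node_paths()
        if path != "root" and path.count(".") == level - 1
    ]
    return partition, labels


def read_labels(path) -> tuple[Partition, list[str]]:
    """Ground-truth two-column table ``sample_id<TAB>label``.

    Returns the partition (types ordered by first appearance) and the type
    labels in the same order.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns, got {df.shape[1]}")
    sample_col, label_col = df.columns
    blocks: dict[str, list[str]] = {}
    order: list[str] = []
    for sid, lab in zip(df[sample_col], df[label_col]):
        if lab not in blocks:
            blocks[lab] = []
            order.append(lab)
        blocks[lab].append(sid)
    return Partition([blocks[lab] for lab in order]), order


def write_curve(curve: EntropyCurve, path) -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        fh.write("k\tH\tstable\n")
        for k, h, s in zip(curve.ks, curve.entropies, curve.stable):
            fh.write(f"{k}\t{h:.12g}\t{int(s)}\n")


def read_curve(path) -> EntropyCurve:
    df = pd.read_csv(path, sep="\t")
    return EntropyCurve(
        [int(k) for k in df["k"]],
        [float(h) for h in df["H"]],
        [bool(int(s)) for s in df["stable"]],
    )
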