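"""End-to-end pipeline: expression -> network -> tree -> gene map -> similarity."""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field, asdict

import pandas as pd

from . import __version__
from .genemap import gene_map, normalise_matrix, partition_similarity
from .graph import write_edge_list
from .io import (
    read_expression,
    read_labels,
    tree_partition_table,
    write_curve,
    write_partition_table,
)
from .minimize import minimize_entropy
from .network import build_network
from .tree import tree_entropy

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Validated parameter set for one pipeline run."""

    expr_path: str
    out_prefix: str
    K: int = 2
    k: int | None = None
    kmin: int = 2
    kmax: int | None = None
    sigma: float | None = None
    modifier: float | None = None
    weight_mode: str = "raw"
    similarity_metric: str = "jaccard"
    truth_path: str | None = None
    impute_missing: bool = False

    def validate(self) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.k is not None and self.k < 1:
            raise ValueError("k must be >= 1")
        if self.weight_mode not in ("raw", "amplified"):
            raise ValueError("weight_mode must be 'raw' or 'amplified'")
        if self.similarity_metric not in ("jaccard", "recall"):
            raise ValueError("similarity_metric must be 'jaccard' or 'recall'")
        if not os.path.exists(self.expr_path):
            raise FileNotFoundError(self.expr_path)
        if self.truth_path is not None and not os.path.exists(self.truth_path):
            raise FileNotFoundError(self.truth_path)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write all artefacts under the out prefix.

    Artefacts: ``<prefix>.graph.tsv`` (edge list), ``<prefix>.curve.tsv``
    (k-scan, when k was selected), ``<prefix>.tree.json``,
    ``<prefix>.modules.tsv`` (sample -> dotted module path at the deepest
    level), ``<prefix>.genemap.tsv`` + ``.genemap.json`` (reordered coded
    matrix and block boundaries), ``<prefix>.similarity.tsv`` (when truth
    labels are supplied) and ``<prefix>.manifest.json``.  Returns the
    manifest.  On failure, partially written artefacts are removed.
    """
    config.validate()
    prefix = config.out_prefix
    os.makedirs(os.path.dirname(os.path.abspath(prefix)), exist_ok=True)
    written: list[str] = []

    def out(suffix: str) -> str:
        path = f"{prefix}.{suffix}"
        written.append(path)
        return path

    stage = "ingest"
    try:
        expr = read_expression(config.expr_path, impute_missing=config.impute_missing)

        stage = "network"
        graph, report = build_network(
            expr,
            k=config.k,
            kmin=config.kmin,
            kmax=config.kmax,
            sigma=config.sigma,
            modifier=config.modifier,
            weight_mode=config.weight_mode,
        )
        write_edge_list(graph, out("graph.tsv"))
        if report.curve is not None:
            write_curve(report.curve, out("curve.tsv"))

        stage = "partition"
        tree = minimize_entropy(graph, config.K)
        tree.to_json(out("tree.json"))
        partition, labels = tree_partition_table(tree, config.K - 1)
        write_partition_table(partition, out("modules.tsv"), labels=labels)

        stage = "genemap"
        norm = normalise_matrix(expr)
        gmap = gene_map(norm, tree, level=config.K - 1)
        gmap.matrix.to_csv(out("genemap.tsv"), sep="\t", index_label="gene_id", lineterminator="\n")
        with open(out("genemap.json"), "wt", encoding="utf-8", newline="\n") as fh:
            json.dump(
                {
                    "group_labels": gmap.group_labels,
                    "row_boundaries": gmap.row_boundaries,
                    "col_boundaries": gmap.col_boundaries,
                    "sample_groups": gmap.sample_groups,
                },
                fh,
                indent=1,
            )
            fh.write("\n")

        similarity_summary = None
        if config.truth_path is not None:
            stage = "similarity"
            truth, truth_order = read_labels(config.truth_path)
            table = partition_similarity(
                partition, truth, metric=config.similarity_metric, truth_labels=truth_order
            )
            table.to_frame().to_csv(out("similarity.tsv"), sep="\t", index=False, lineterminator="\n")
            similarity_summary = {
                "weighted_average": table.weighted_average,
                "per_type": dict(zip(table.true_labels, table.scores)),
            }

        stage = "manifest"
        manifest = {
            "version": __version__,
            "config": asdict(config),
            "network": report.to_dict() | {"curve": None},  # full curve lives in curve.tsv
            "n_modules": partition.n_blocks,
            "tree_height": tree.height,
            "tree_entropy_bits": tree_entropy(graph, tree) if graph.volume > 0 else None,
            "similarity": similarity_summary,
            "artefacts": [os.path.basename(p) for p in written] + [
                os.path.basename(f"{prefix}.manifest.json")
            ],
        }
        with open(out("manifest.json"), "wt", encoding="utf-8", newline="\n") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return manifest
    except Exception as exc:
        for path in written:
            if os.path.exists(path):
                os.remove(path)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
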