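"""Synthetic generators with planted ground truth.

Everything is driven by a single seeded :class:`numpy.random.Generator`, so
identical parameters and seed reproduce byte-identical objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graph import WeightedGraph
from .tree import Partition

__all__ = [
    "PlantedTruth",
    "planted_partition_graph",
    "hierarchical_planted_graph",
    "synthetic_expression",
]


@dataclass
class PlantedTruth:
    """Ground-truth labels for a generated graph or expression matrix."""

    labels: list[str]
    level1: list[int]  # class index per label
    level2: list[int] | None = None  # finer class index per label, if planted
    params: dict = field(default_factory=dict)

    def partition(self, level: int = 1) -> Partition:
        classes = self.level1 if level == 1 else self.level2
        if classes is None:
            raise ValueError(f"no level-{level} truth recorded")
        blocks: dict[int, list[str]] = {}
        for label, c in zip(self.labels, classes):
            blocks.setdefault(c, []).append(label)
        return Partition([blocks[c] for c in sorted(blocks)])

    def to_frame(self) -> pd.DataFrame:
        data = {"id": self.labels, "level1": self.level1}
        if self.level2 is not None:
            data["level2"] = self.level2
        return pd.DataFrame(data)


def _bernoulli_graph(
    labels: list[str],
    prob: np.ndarray,
    rng: np.random.Generator,
    weight_jitter: float,
) -> WeightedGraph:
    n = len(labels)
    graph = WeightedGraph(labels)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < prob[i, j]:
                w = 1.0
                if weight_jitter > 0:
                    w += rng.uniform(-weight_jitter, weight_jitter)
                graph.add_edge(labels[i], labels[j], max(w, 1e-9))
    if len(graph.connected_components()) > 1:
        warnings.warn("generated graph is disconnected")
    return graph


def planted_partition_graph(
    block_sizes: list[int],
    p_in: float,
    p_out: float,
    *,
    seed: int = 0,
    weight_jitter: float = 0.0,
) -> tuple[WeightedGraph, PlantedTruth]:
    """Planted-partition random graph: p_in within blocks, p_out between."""
    if not 0 <= p_out < p_in <= 1:
        raise ValueError("require 0 <= p_out < p_in <= 1")
    rng = np.random.default_rng(seed)
    labels, classes = [], []
    for b, size in enumerate(block_sizes):
        for i in range(size):
            labels.append(f"v{len(labels) + 1}")
            classes.append(b)
    cls = np.array(classes)
    prob = np.where(cls[:, None] == cls[None, :], p_in, p_out)
    graph = _bernoulli_graph(labels, prob, rng, weight_jitter)
    truth = PlantedTruth(
        labels,
        classes,
        params={
            "block_sizes": list(block_sizes),
            "p_in": p_in,
            "p_out": p_out,
            "seed": seed,
            "weight_jitter": weight_jitter,
        },
    )
    return graph, truth


def hierarchical_planted_graph(
    submodule_sizes: list[list[int]],
    p_sub: float,
    p_mod: float,
    p_out: float,
    *,
    seed: int = 0,
    weight_jitter: float = 0.0,
) -> tuple[WeightedGraph, PlantedTruth]:
    """Two-level planted graph with three connection tiers.

    ``submodule_sizes[m]`` lists the submodule sizes inside module ``m``;
    edges appear with probability ``p_sub`` inside a submodule, ``p_mod``
    between submodules of one module, and ``p_out`` across modules.
    """
    if not 0 <= p_out < p_mod < p_sub <= 1:
        raise ValueError("require 0 <= p_out < p_mod < p_sub <= 1")
    rng = np.random.default_rng(seed)
    labels, mods, subs = [], [], []
    sub_counter = 0
    for m, sizes in enumerate(submodule_sizes):
        for size in sizes:
            for _ in range(size):
                labels.append(f"v{len(labels) + 1}")
                mods.append(m)
                subs.append(sub_counter)
            sub_counter += 1
    mod_arr, sub_arr = np.array(mods), np.array(subs)
    prob = np.where(
        sub_arr[:, None] == sub_arr[None, :],
        p_sub,
        np.where(mod_arr[:, None] == mod_arr[None, :], p_mod, p_out),
    )
    graph = _bernoulli_graph(labels, prob, rng, weight_jitter)
    truth = PlantedTruth(
        labels,
        mods,
        subs,
        params={
            "submodule_sizes": [list(s) for s in submodule_sizes],
            "p_sub": p_sub,
            "p_mod": p_mod,
            "p_out": p_out,
            "seed": seed,
            "weight_jitter": weight_jitter,
        },
    )
    return graph, truth


def synthetic_expression(
    n_groups: int,
    samples_per_group: int,
    n_genes: int,
    signal_genes_per_group: int,
    *,
    effect: float = 1.0,
    noise_sd: float = 0.2,
    baseline: float = 0.0,
    gene_baseline_sd: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Block-structured expression matrix with planted sample groups.

    Each group owns a disjoint set of signal genes that are over-expressed
    (by ``effect``) in that group's samples; i.i.d. Gaussian noise is added
    everywhere.  The signal gene ids for group ``j`` (0-based) are rows
    ``j*signal_genes_per_group .. (j+1)*signal_genes_per_group - 1``.

    On top of the scalar ``baseline``, every gene carries a random
    per-gene baseline (sd ``gene_baseline_sd``) shared by all samples.
    This mimics the gene-to-gene abundance spread of real expression
    platforms and gives unrelated samples the positive background
    correlation observed there; set it to 0 for a pure block design.
    """
    if effect < 0:
        raise ValueError("effect must be >= 0")
    if n_groups * signal_genes_per_group > n_genes:
        raise ValueError("signal gene sets exceed the gene count")
    rng = np.random.default_rng(seed)
    n_samples = n_groups * samples_per_group
    sample_ids = [f"s{i + 1}" for i in range(n_samples)]
    gene_ids = [f"g{i + 1}" for i in range(n_genes)]
    group_of = [i // samples_per_group for i in range(n_samples)]

    values = np.full((n_genes, n_samples), baseline, dtype=float)
    if gene_baseline_sd > 0:
        values += rng.normal(0.0, gene_baseline_sd, size=n_genes)[:, None]
    for g in range(n_groups):
        rows = slice(g * signal_genes_per_group, (g + 1) * signal_genes_per_group)
        cols = [i for i, grp in enumerate(group_of) if grp == g]
        values[rows, cols[0] : cols[-1] + 1] += effect
    if noise_sd > 0:
        values += rng.normal(0.0, noise_sd, size=values.shape)

    expr = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    truth = PlantedTruth(
        sample_ids,
        group_of,
        params={
            "n_groups": n_groups,
            "samples_per_group": samples_per_group,
            "n_genes": n_genes,
            "signal_genes_per_group": signal_genes_per_group,
            "effect": effect,
            "noise_sd": noise_sd,
            "baseline": baseline,
            "gene_baseline_sd": gene_baseline_sd,
            "seed": seed,
        },
    )
    return expr, truth
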