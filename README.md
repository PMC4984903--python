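# structent

Structural-entropy minimisation for weighted networks, with an end-to-end
pipeline that turns a gene-expression matrix (genes × samples) into a
cell-sample network, detects modules (K = 2) and submodules (K = 3) by
greedy K-dimensional structural-entropy minimisation, and builds a gene map
that assigns every gene to the sample group it most strongly expresses.

## What is inside

| module                 | contents |
|------------------------|----------|
| `structent.graph`      | `WeightedGraph`, random-walk stationary distribution, one-dimensional structural entropy (volume-weighted over components), edge-list TSV I/O |
| `structent.tree`       | `PartitioningTree` / `Partition`, two-dimensional partition entropy, general tree entropy, level partitions, unary padding to uniform height, tree JSON |
| `structent.minimize`   | merging / combining operators, locally computable entropy deltas, the greedy height-K minimiser, a Bell-number brute-force oracle (n ≤ 10) |
| `structent.network`    | pairwise Pearson weights, noise-amplifying modifier, union-symmetrised top-k graphs, the H(k) entropy curve, stable-point selection of k, `build_network` |
| `structent.genemap`    | per-gene coding (mean 0, range ⊆ [−1, 1]), group mean expression, arg-max gene block assignment, reordered gene-map matrix, Jaccard/recall partition similarity |
| `structent.simulate`   | seeded planted-partition graphs, two-level hierarchical graphs, block-structured synthetic expression matrices with ground truth |
| `structent.io`         | TSV/CSV/GCT expression readers, partition and curve tables |
| `structent.pipeline`   | `RunConfig` + `run_pipeline` (network → tree → gene map → similarity → manifest) |
| `structent.cli`        | the `structent` command |

The two displayed entropy equations in the source material are not
reproduced there; the canonical forms implemented here are reconstructed
from the printed symbol definitions:

```
H_partition = Σ_j (Vol_j/vol)·H(d_i/Vol_j) + Σ_j (g_j/vol)·log2(vol/Vol_j)
H_tree      = Σ_{α ≠ root} (g_α/vol)·log2(V_parent(α)/V_α)
```

and their algebraic identity on height-2 trees is a standing regression
test.  The same applies to the noise-amplifier σ (the shipped default
implements the stated equivalent rule `M = 1/(n−1)` for n < 1000, `1/n`
otherwise) and to the similarity function (Jaccard by default, recall
variant behind `--metric recall`).

## CLI

```sh
# synthetic data with ground truth
structent simulate expr --groups 3 --samples-per-group 12 --genes 600 \
    --signal-genes 100 --seed 1 --out expr.tsv --truth truth.tsv

# sample network with automatic k selection
structent buildnet --expr expr.tsv --out graph.tsv --curve curve.tsv --report report.json

# greedy structural-entropy partitioning (K = 2 modules, K = 3 submodules)
structent partition --graph graph.tsv --K 2 --out tree.json \
    --modules modules.tsv --emit-entropy trace.tsv

# gene map and similarity to ground truth
structent genemap --expr expr.tsv --tree tree.json --level 1 --out-prefix gm
structent similarity --found modules.tsv --truth labels.tsv --out sim.tsv

# everything in one go
structent pipeline --expr expr.tsv --out-prefix run --K 2 --truth labels.tsv
```

`simulate graph` and `simulate hgraph` produce planted one- and two-level
community graphs as edge-list TSVs plus truth tables.

## File formats

* expression: TSV/CSV with gene ids in column 1 and sample ids in the
  header, or GCT (`#1.2` preamble, Name/Description columns);
* graphs: three-column `source  target  weight` TSV, undirected;
* trees: nested JSON `{label, children:[...]}` with leaves
  `{label, vertex}`; labels are 1-based dotted paths ("2.1" = first
  submodule of module 2);
* partitions: two-column `sample_id  module_path` TSV;
* entropy curves: `k  H  stable` TSV.
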