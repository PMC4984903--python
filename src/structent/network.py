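"""Cell-sample network construction from expression matrices.

The sample network over an expression matrix (genes x samples) is a top-k
nearest-neighbour graph under pairwise Pearson correlation of the sample
profiles.  The neighbour count ``k`` is chosen by scanning one-dimensional
structural entropy: a constant *modifier* ``M = sigma * mean(W)`` is first
added to every pairwise weight (amplifying trivial/noisy weights relative
to strong ones), the top-k graph is built for each candidate ``k``, and the
*stable point* — an interior strict local minimum of the entropy curve
``H(k)`` — with least entropy wins.

The printed closed forms for ``sigma`` are not reproduced in the source
text; the default modifier implements the stated equivalent operation
(each sample spreads one extra unit of weight uniformly over the others):
``M = 1/(n-1)`` for ``n < 1000`` and ``M = 1/n`` otherwise.  Both ``sigma``
and ``M`` can be overridden.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .graph import WeightedGraph, one_dim_entropy

__all__ = [
    "pearson_weights",
    "amplify",
    "topk_graph",
    "entropy_curve",
    "select_k",
    "build_network",
    "EntropyCurve",
    "NetworkReport",
]


def pearson_weights(expr: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation between sample (column) profiles.

    Returns a symmetric samples x samples table with NaN on the diagonal
    (self-pairs are never edges).  A zero-variance sample profile is an
    error, since its correlations are undefined.
    """
    values = expr.to_numpy(dtype=float)
    if np.isnan(values).any():
        bad = expr.columns[np.isnan(values).any(axis=0)].tolist()
        raise ValueError(f"missing values in expression matrix (samples {bad})")
    stds = values.std(axis=0)
    zero_var = np.flatnonzero(stds == 0)
    if zero_var.size:
        names = [str(expr.columns[i]) for i in zero_var]
        raise ValueError(f"zero-variance sample profile(s): {', '.join(names)}")
    corr = np.corrcoef(values, rowvar=False)
    np.fill_diagonal(corr, np.nan)
    return pd.DataFrame(corr, index=expr.columns, columns=expr.columns)


def amplify(
    weights: pd.DataFrame,
    *,
    sigma: float | None = None,
    modifier: float | None = None,
) -> tuple[pd.DataFrame, float, float]:
    """Add the noise-amplifying modifier ``M`` to every pairwise weight.

    Returns ``(amplified_weights, M, mean_weight)``.  Precedence: explicit
    ``modifier`` > explicit ``sigma`` (then ``M = sigma * mean``) > default
    rule ``M = 1/(n-1)`` if ``n < 1000`` else ``1/n``.  The mean weight is
    taken over distinct sample pairs (diagonal excluded).
    """
    n = weights.shape[0]
    if n < 2:
        raise ValueError("need at least two samples")
    arr = weights.to_numpy(dtype=float)
    iu = np.triu_indices(n, k=1)
    w_bar = float(np.mean(arr[iu]))
    if modifier is not None:
        m = float(modifier)
    elif sigma is not None:
        m = float(sigma) * w_bar
    else:
        m = 1.0 / (n - 1) if n < 1000 else 1.0 / n
    out = weights + m
    return out, m, w_bar


def _top_neighbors(row: np.ndarray, k: int) -> list[int]:
    """Indices of the k largest finite weights; ties favour input order."""
    valid = np.flatnonzero(~np.isnan(row))
    # stable sort on (-weight); equal weights keep ascending index order
    order = valid[np.argsort(-row[valid], kind="stable")]
    return order[:k].tolist()


def topk_graph(weights: pd.DataFrame, k: int) -> WeightedGraph:
    """Union-symmetrised top-k graph over a pairwise weight table.

    An edge (i, j) is kept if j is among i's k strongest correlations or
    vice versa; retained edges carry the table's weights.  Edges whose
    weight is not strictly positive are dropped (entropy needs positive
    volume), so vertices can end up isolated.
    """
    n = weights.shape[0]
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")
    arr = weights.to_numpy(dtype=float)
    labels = [str(c) for c in weights.columns]
    graph = WeightedGraph(labels)
    selected: set[tuple[int, int]] = set()
    for i in range(n):
        for j in _top_neighbors(arr[i], k):
            selected.add((i, j) if i < j else (j, i))
    dropped = 0
    for i, j in sorted(selected):
        w = arr[i, j]
        if w > 0:
            graph.add_edge(labels[i], labels[j], w)
        else:
            dropped += 1
    if dropped:
        warnings.warn(f"dropped {dropped} non-positive-weight edges from top-{k} graph")
    return graph


@dataclass
class EntropyCurve:
    """One-dimensional entropy of the top-k graph as a function of k."""

    ks: list[int]
    entropies: list[float]
    stable: list[bool] = field(default_factory=list)

    def __post_init__(self):
        if any(b >= a for a, b in zip(self.ks[1:], self.ks)):
            raise ValueError("k values must be strictly increasing")
        if not self.stable:
            self.stable = self._find_stable()

    def _find_stable(self) -> list[bool]:
        flags = [False] * len(self.ks)
        for i in range(1, len(self.ks) - 1):
            if self.ks[i - 1] == self.ks[i] - 1 and self.ks[i + 1] == self.ks[i] + 1:
                if self.entropies[i - 1] > self.entropies[i] < self.entropies[i + 1]:
                    flags[i] = True
        return flags

    def stable_points(self) -> list[int]:
        return [k for k, f in zip(self.ks, self.stable) if f]

    def __iter__(self):
        return iter(zip(self.ks, self.entropies))


def entropy_curve(weights: pd.DataFrame, k_range: Sequence[int]) -> EntropyCurve:
    """Evaluate H(k) = one-dimensional entropy of the top-k graph.

    ``weights`` should normally be the amplified table; stable points are
    strict interior local minima of the curve.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k range")
    n = weights.shape[0]
    if ks[0] < 1 or ks[-1] > n - 1:
        raise ValueError(f"k range must lie within [1, {n - 1}]")
    entropies = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # non-positive-edge drops are routine here
        for k in ks:
            entropies.append(one_dim_entropy(topk_graph(weights, k)))
    return EntropyCurve(ks, entropies)


def select_k(curve: EntropyCurve) -> int:
    """Stable point of least entropy; ties toward the smallest k.

    Falls back (with a warning) to the global argmin of H when the curve
    has no stable point at all.
    """
    best_k: int | None = None
    best_h = np.inf
    for k, h, flag in zip(curve.ks, curve.entropies, curve.stable):
        if flag and h < best_h:
            best_h = h
            best_k = k
    if best_k is not None:
        return best_k
    warnings.warn("no stable point in entropy curve; using global minimum of H(k)")
    i = int(np.argmin(curve.entropies))
    return curve.ks[i]


@dataclass
class NetworkReport:
    n_samples: int
    mean_weight: float
    modifier: float
    curve: EntropyCurve | None
    stable_points: list[int]
    chosen_k: int
    weight_mode: str

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "mean_weight": self.mean_weight,
            "modifier": self.modifier,
            "curve": (
                [
                    {"k": k, "H": h, "stable": s}
                    for k, h, s in zip(self.curve.ks, self.curve.entropies, self.curve.stable)
                ]
                if self.curve is not None
                else None
            ),
            "stable_points": self.stable_points,
            "chosen_k": self.chosen_k,
            "weight_mode": self.weight_mode,
        }


def build_network(
    expr: pd.DataFrame,
    *,
    k: int | None = None,
    kmin: int = 2,
    kmax: int | None = None,
    sigma: float | None = None,
    modifier: float | None = None,
    weight_mode: str = "raw",
) -> tuple[WeightedGraph, NetworkReport]:
    """End-to-end sample network construction.

    When ``k`` is not given it is selected via the amplified entropy curve
    over ``k in [kmin, min(kmax, n-1)]`` (default ``kmax`` 50).  The output
    graph keeps raw Pearson weights unless ``weight_mode='amplified'``.
    """
    if weight_mode not in ("raw", "amplified"):
        raise ValueError("weight_mode must be 'raw' or 'amplified'")
    raw = pearson_weights(expr)
    n = raw.shape[0]
    amped, m, w_bar = amplify(raw, sigma=sigma, modifier=modifier)
    curve = None
    if k is None:
        hi = min(kmax if kmax is not None else 50, n - 1)
        lo = max(1, kmin)
        if lo > hi:
            raise ValueError(f"empty k scan range [{lo}, {hi}]")
        curve = entropy_curve(amped, range(lo, hi + 1))
        k = select_k(curve)
    table = raw if weight_mode == "raw" else amped
    graph = topk_graph(table, k)
    report = NetworkReport(
        n_samples=n,
        mean_weight=w_bar,
        modifier=m,
        curve=curve,
        stable_points=curve.stable_points() if curve is not None else [],
        chosen_k=int(k),
        weight_mode=weight_mode,
    )
    return graph, report
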