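"""Network statistics: stability, node strength, cluster size.

Three analysis statistics used to compare trained networks with random
baselines and real connectomes:

* **stability RMSE** — pairwise root-mean-square error between the
  ordered, mean-normalized weight vectors of replicate networks; small
  values mean runs under the same condition converge to statistically
  similar weight profiles;
* **node-strength distribution** — the cumulative distribution of
  ``s_i = sum_j |w_ij|`` sampled at 100 quantile points and normalized
  by the maximum, the weighted analogue of a degree distribution;
* **cluster curves** — the maximum single-node neighborhood size in
  subnetworks built from the top ``r * n_c`` strongest connections, as
  a function of the connection ratio ``r``; hub-dominated networks keep
  large clusters down to small ``r``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "StrengthDistribution",
    "ClusterCurve",
    "node_strength",
    "strength_distribution",
    "stability_rmse",
    "max_cluster_size",
    "cluster_curve",
    "degree_product_weights",
]


def node_strength(W) -> np.ndarray:
    """Node strength ``s_i = sum_j |w_ij|`` (the wiring cost, under its
    graph-theoretic name)."""
    W = np.asarray(W, dtype=float)
    return np.abs(W).sum(axis=1)


@dataclass(frozen=True)
class StrengthDistribution:
    """Cumulative node-strength distribution sampled at quantile points.

    ``probabilities[n] = (n+1)/(n_points+1)``; ``strengths`` are the
    corresponding order statistics normalized by the maximum strength,
    nonincreasing along the sequence.
    """

    probabilities: np.ndarray
    strengths: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"probability": self.probabilities, "strength": self.strengths}
        )

    @property
    def value_range(self) -> float:
        """min/max ratio of the sampled normalized strengths; smaller
        means a wider (heavier-tailed) distribution."""
        return float(self.strengths.min() / self.strengths.max())


def strength_distribution(values, n_points: int = 100) -> StrengthDistribution:
    """Sample the ordered strengths at 100 evenly spaced quantiles.

    Values are ordered descending ``s(0) >= s(1) >= ...``; point ``n``
    takes the element at the order nearest ``((n+1)/(n_points+1)) * N``
    and is paired with cumulative probability ``(n+1)/(n_points+1)``.
    All values are normalized by the maximum.  When the input has fewer
    than ``n_points`` entries (e.g. a 65-node connectome), every value
    is used instead.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("empty strength vector")
    if values.max() <= 0:
        raise ValueError("degenerate (all-zero) strength distribution")
    s = np.sort(values)[::-1]
    N = s.size
    if N < n_points:
        idx = np.arange(N)
        prob = (idx + 1) / (N + 1)
    else:
        n = np.arange(n_points)
        idx = np.clip(np.rint((n + 1) / (n_points + 1) * N).astype(int), 0, N - 1)
        prob = (n + 1) / (n_points + 1)
    return StrengthDistribution(probabilities=prob, strengths=s[idx] / s[0])


def _ordered_normalized(W) -> np.ndarray:
    w = np.abs(np.asarray(W, dtype=float)).ravel()
    m = w.mean()
    if m == 0:
        raise ValueError("all-zero network has no normalized weight order")
    return np.sort(w)[::-1] / m


def stability_rmse(networks) -> float:
    """Average pairwise RMSE between ordered, mean-normalized weights.

    For each network the |w| values are flattened, sorted descending and
    divided by their mean; the RMSE is computed between these ordered
    vectors for every unordered pair of networks and averaged.  Zero for
    identical networks and invariant to weight permutations and global
    rescaling within each network.
    """
    networks = list(networks)
    if len(networks) < 2:
        raise ValueError("stability RMSE needs at least 2 networks")
    shapes = [np.asarray(n).shape for n in networks]
    for k, shape in enumerate(shapes[1:], start=1):
        if shape != shapes[0]:
            raise ValueError(
                f"shape mismatch between network 0 {shapes[0]} and "
                f"network {k} {shape}"
            )
    ordered = [_ordered_normalized(n) for n in networks]
    rmses = [
        float(np.sqrt(np.mean((a - b) ** 2)))
        for a, b in combinations(ordered, 2)
    ]
    return float(np.mean(rmses))


def _offdiag_edges(W):
    """Sorted off-diagonal nonzero entries: (rows, cols) by descending
    |w|, ties broken by (row, col) index for determinism."""
    W = np.asarray(W, dtype=float)
    mask = W != 0.0
    np.fill_diagonal(mask, False)
    rows, cols = np.nonzero(mask)
    w = np.abs(W[rows, cols])
    # lexsort: last key is primary; negate for descending strength
    order = np.lexsort((cols, rows, -w))
    return rows[order], cols[order]


def _max_neighbor_count(rows, cols, n_nodes: int) -> int:
    if rows.size == 0:
        return 0
    # undirected neighbor count on the subnetwork's support
    pair_i = np.concatenate([rows, cols])
    pair_j = np.concatenate([cols, rows])
    # dedupe (i, j) pairs so mutual edges count the partner once
    keys = np.unique(pair_i.astype(np.int64) * n_nodes + pair_j)
    counts = np.bincount((keys // n_nodes).astype(int), minlength=n_nodes)
    return int(counts.max())


def max_cluster_size(W, r: float) -> int:
    """Maximum single-node neighborhood size in the top-``r`` subnetwork.

    The subnetwork keeps the ``floor(r * n_c)`` strongest connections by
    |w| (``n_c`` = number of nonzero off-diagonal weights); each node's
    cluster is the set of distinct partners connected to it in either
    direction, and the maximum count over nodes is returned.  Returns 0
    when ``r * n_c < 1``.
    """
    if not 0.0 < r <= 1.0:
        raise ValueError(f"connection ratio r must be in (0, 1], got {r}")
    W = np.asarray(W, dtype=float)
    rows, cols = _offdiag_edges(W)
    n_c = rows.size
    k = int(np.floor(r * n_c))
    if k < 1:
        return 0
    return _max_neighbor_count(rows[:k], cols[:k], W.shape[0])


@dataclass(frozen=True)
class ClusterCurve:
    """Normalized maximum cluster size vs connection ratio ``r``.

    ``sizes`` are normalized by the full-network (r = 1) value, so the
    curve is nondecreasing and ends at 1.
    """

    ratios: np.ndarray
    sizes: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"ratio": self.ratios, "size": self.sizes})

    def at(self, r: float) -> float:
        """Curve value at the grid point nearest ``r``."""
        return float(self.sizes[np.argmin(np.abs(self.ratios - r))])


def cluster_curve(W, r_step: float = 0.01) -> ClusterCurve:
    """Evaluate :func:`max_cluster_size` over ``r = r_step ... 1``.

    The edge ranking is computed once and reused across the grid.
    """
    if not 0.0 < r_step <= 1.0:
        raise ValueError(f"r_step must be in (0, 1], got {r_step}")
    W = np.asarray(W, dtype=float)
    rows, cols = _offdiag_edges(W)
    n_c = rows.size
    if n_c == 0:
        raise ValueError("network has no off-diagonal connections")
    n_steps = int(round(1.0 / r_step))
    ratios = np.arange(1, n_steps + 1) * r_step
    ratios[-1] = 1.0
    sizes = np.empty(ratios.size)
    for i, r in enumerate(ratios):
        k = int(np.floor(r * n_c))
        sizes[i] = _max_neighbor_count(rows[:k], cols[:k], W.shape[0]) if k >= 1 else 0
    full = sizes[-1]
    if full == 0:
        raise ValueError("full network has maximum cluster size 0")
    return ClusterCurve(ratios=ratios, sizes=sizes / full)


def degree_product_weights(A) -> np.ndarray:
    """Degree-product weighting for binary topological networks.

    Given a 0/1 adjacency matrix, returns ``w(i,j) = d(i) * d(j)`` on
    existing edges and 0 elsewhere, where ``d(i)`` is the number of
    distinct partners of node *i* in either direction (self-connections
    excluded).  Lets strength-based procedures run on networks that only
    record topology.
    """
    A = np.asarray(A, dtype=float)
    uniq = np.unique(A)
    if not np.all(np.isin(uniq, (0.0, 1.0))):
        raise ValueError(
            "degree-product weighting requires a binary (0/1) matrix; "
            "use the raw weights for weighted networks"
        )
    support = (A != 0) | (A.T != 0)
    np.fill_diagonal(support, False)
    d = support.sum(axis=1).astype(float)
    W = np.outer(d, d)
    mask = A != 0
    np.fill_diagonal(mask, False)
    return np.where(mask, W, 0.0)
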