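"""Connectivity-matrix I/O and synthetic connectome fixtures.

Two plain-text formats are supported for external connectomes:

* ``dense_csv`` — a header-free, comma-separated square matrix, row *i*
  holding the outgoing weights of node *i*;
* ``edge_list`` — a 3-column CSV with header ``source,target,weight``
  and 0-based integer node ids; absent pairs are 0.

No download code is included: point :func:`read_matrix` at files you
obtained yourself (e.g. region-level human connectivity matrices or
neuron-level animal connectomes).  :func:`synth_connectome` generates
connectome-like matrices with a tunable heavy-tail so every comparison
path can be exercised offline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ConnectomeRecord", "read_matrix", "write_matrix", "synth_connectome"]

FORMATS = ("dense_csv", "edge_list")


@dataclass(frozen=True)
class ConnectomeRecord:
    """A loaded or generated connectivity matrix with provenance.

    ``node_kind`` distinguishes region-level (e.g. imaging-derived) from
    neuron-level (synaptic) networks; ``is_binary`` is true when every
    entry is 0 or 1, in which case strength-based procedures should go
    through :func:`enform.metrics.degree_product_weights`.
    """

    matrix: np.ndarray
    label: str = ""
    node_kind: str = "region"
    is_binary: bool = False

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]


def _detect_binary(W: np.ndarray) -> bool:
    return bool(np.all(np.isin(np.unique(W), (0.0, 1.0))))


def read_matrix(path, format: str = "dense_csv", label: str | None = None,
                node_kind: str = "region") -> ConnectomeRecord:
    """Read a connectivity matrix from disk.

    Parameters
    ----------
    path : path-like
    format : {'dense_csv', 'edge_list'}
    label : str, optional
        Defaults to the file stem.
    node_kind : {'region', 'neuron'}

    Raises
    ------
    ValueError
        Non-square dense input, non-numeric cells or negative node ids,
        naming the offending row/column; empty files.
    """
    path = Path(path)
    if format not in FORMATS:
        raise ValueError(f"format must be one of {FORMATS}, got {format!r}")
    if label is None:
        label = path.stem

    if format == "dense_csv":
        try:
            df = pd.read_csv(path, header=None)
        except pd.errors.EmptyDataError:
            raise ValueError(f"{path}: empty file") from None
        bad = df.columns[df.apply(
            lambda c: pd.to_numeric(c, errors="coerce").isna() & c.notna()
        ).any()]
        if len(bad):
            raise ValueError(f"{path}: non-numeric cells in column(s) {list(bad)}")
        W = df.to_numpy(dtype=float)
        if W.shape[0] != W.shape[1]:
            raise ValueError(
                f"{path}: dense matrix must be square, got "
                f"{W.shape[0]} rows x {W.shape[1]} columns"
            )
    else:
        try:
            df = pd.read_csv(path)
        except pd.errors.EmptyDataError:
            raise ValueError(f"{path}: empty file") from None
        expected = ["source", "target", "weight"]
        if list(df.columns[:3]) != expected:
            raise ValueError(
                f"{path}: edge list must have header {expected}, "
                f"got {list(df.columns)}"
            )
        if df.empty:
            raise ValueError(f"{path}: edge list has no edges")
        src = df["source"].to_numpy()
        dst = df["target"].to_numpy()
        for name, ids in (("source", src), ("target", dst)):
            if not np.issubdtype(ids.dtype, np.integer):
                raise ValueError(f"{path}: {name} ids must be integers")
            if (ids < 0).any():
                row = int(np.argmax(ids < 0))
                raise ValueError(f"{path}: negative {name} id at data row {row}")
        n = int(max(src.max(), dst.max())) + 1
        W = np.zeros((n, n))
        W[src, dst] = df["weight"].to_numpy(dtype=float)

    return ConnectomeRecord(
        matrix=W, label=label, node_kind=node_kind, is_binary=_detect_binary(W)
    )


def write_matrix(W, path, format: str = "dense_csv") -> Path:
    """Write a matrix in either supported format (edge lists keep only
    nonzero entries)."""
    path = Path(path)
    W = np.asarray(W, dtype=float)
    if format == "dense_csv":
        np.savetxt(path, W, delimiter=",")
    elif format == "edge_list":
        rows, cols = np.nonzero(W)
        pd.DataFrame(
            {"source": rows, "target": cols, "weight": W[rows, cols]}
        ).to_csv(path, index=False)
    else:
        raise ValueError(f"format must be one of {FORMATS}, got {format!r}")
    return path


def synth_connectome(n_nodes: int, hubness: float = 1.0, density: float = 0.3,
                     seed: int = 0, binary: bool = False,
                     label: str = "synthetic") -> ConnectomeRecord:
    """Generate a synthetic connectome-like matrix (a stand-in fixture,
    not derived from any measured brain).

    Node propensities ``x_i`` are drawn from a lognormal with sigma =
    ``hubness``; the expected weight of edge (i, j) is proportional to
    ``x_i * x_j``, so larger ``hubness`` yields heavier-tailed node
    strengths (``hubness = 0`` gives approximately uniform strengths).
    Edges are kept independently with probability ``density``; the
    diagonal is zero.

    Parameters
    ----------
    n_nodes : int
    hubness : float >= 0
    density : float in (0, 1]
    seed : int
    binary : bool
        If true, return the 0/1 support instead of weights (topological
        connectome, e.g. a synapse-presence map).
    """
    if n_nodes <= 0:
        raise ValueError(f"n_nodes must be positive, got {n_nodes}")
    if hubness < 0:
        raise ValueError(f"hubness must be >= 0, got {hubness}")
    if not 0.0 < density <= 1.0:
        raise ValueError(f"density must be in (0, 1], got {density}")
    rng = np.random.default_rng(seed)
    x = rng.lognormal(mean=0.0, sigma=hubness, size=n_nodes)
    base = np.outer(x, x)
    noise = rng.lognormal(mean=0.0, sigma=0.25, size=(n_nodes, n_nodes))
    W = base * noise
    if density < 1.0:
        keep = rng.random((n_nodes, n_nodes)) < density
        W = np.where(keep, W, 0.0)
    np.fill_diagonal(W, 0.0)
    if binary:
        W = (W != 0.0).astype(float)
    return ConnectomeRecord(
        matrix=W, label=label,
        node_kind="neuron" if binary else "region",
        is_binary=binary,
    )
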