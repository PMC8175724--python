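"""Random input-signal generation.

Input signals model homogeneous external stimuli: each signal vector has
entries in {-1, 0, +1}.  For every vector a sparseness level ``p`` is
drawn uniformly in ``(0, p_max)`` and each entry is then nonzero with
probability ``p``, the sign chosen uniformly (the default
``sign_scheme='split'``).  The alternative reading — each sign
independently with probability ``p``, total nonzero probability ``2p`` —
is available as ``sign_scheme='independent'``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SignalSpec", "generate_signals"]

SIGN_SCHEMES = ("split", "independent")


@dataclass(frozen=True)
class SignalSpec:
    """Specification of a signal pool.

    Parameters
    ----------
    n_signals : int
        Number of signal vectors (1e4 in the reference protocol).
    n_nodes : int
        Dimension N of each vector.
    p_max : float
        Upper end of the uniform range the per-vector sparseness ``p``
        is drawn from; default 0.5.
    seed : int or numpy Generator-compatible seed
    sign_scheme : str
        ``'split'`` (default) or ``'independent'``; see module docstring.
    """

    n_signals: int
    n_nodes: int
    p_max: float = 0.5
    seed: int = 0
    sign_scheme: str = "split"

    def __post_init__(self):
        if self.n_signals <= 0 or self.n_nodes <= 0:
            raise ValueError(
                f"n_signals and n_nodes must be positive, got "
                f"{self.n_signals}, {self.n_nodes}"
            )
        if not 0.0 < self.p_max <= 1.0:
            raise ValueError(f"p_max must be in (0, 1], got {self.p_max}")
        if self.sign_scheme not in SIGN_SCHEMES:
            raise ValueError(f"sign_scheme must be one of {SIGN_SCHEMES}")


def generate_signals(spec: SignalSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Generate a (n_signals, n_nodes) batch of ternary signal vectors.

    One ``p ~ U(0, p_max)`` per vector; entries independent within a
    vector.  Fully reproducible from ``spec.seed`` (or an explicitly
    supplied generator, which takes precedence).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    p = rng.uniform(0.0, spec.p_max, size=(spec.n_signals, 1))
    u = rng.random((spec.n_signals, spec.n_nodes))
    out = np.zeros((spec.n_signals, spec.n_nodes), dtype=np.int8)
    if spec.sign_scheme == "split":
        # nonzero with prob p, sign uniform: +1 on [0, p/2), -1 on [p/2, p)
        out[u < p / 2.0] = 1
        out[(u >= p / 2.0) & (u < p)] = -1
    else:
        # each sign independently with prob p (total 2p, capped below 1
        # by p_max <= 0.5 in the reference protocol)
        out[u < p] = 1
        out[(u >= p) & (u < np.minimum(2.0 * p, 1.0))] = -1
    return out
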