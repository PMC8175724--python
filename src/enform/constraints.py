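"""Boundedness constraints on the weight matrix.

Minimizing the ratio E_a/E_w admits two unphysical escapes: the wiring
cost diverging (infinitely strong connections) and the activity cost
collapsing to zero (dead network).  Two constraints close them off:

* an upper weight bound ``w_u = <|w|> + n_sigma * std(|w|)``, recomputed
  from the current matrix each epoch, with entries ``|w| > w_u`` clipped
  back to ``sign(w) * w_u``;
* an activity floor ``E_a^L = alpha * E_a^0`` (``E_a^0`` measured on the
  initial matrix): when the node-averaged activity cost drops below the
  floor, every weight is rescaled by ``E_a^L / E_a`` — a homeostatic
  scaling step.  Because E_a is homogeneous of degree 3 in W, the rescale
  overshoots the floor; it is applied literally anyway, which still
  serves the constraint's purpose of prohibiting the zero state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LimitConfig",
    "CollapseError",
    "compute_upper_bound",
    "clip_weights",
    "enforce_activity_floor",
]


class CollapseError(RuntimeError):
    """Raised when the activity cost is exactly zero: the homeostatic
    rescale w -> (E_a^L / E_a) w cannot recover a zero state."""


@dataclass(frozen=True)
class LimitConfig:
    """Constraint parameters.

    Parameters
    ----------
    n_sigma : float or None
        Upper-bound multiplier in ``w_u = <|w|> + n_sigma * std(|w|)``;
        ``None`` disables the bound (the no-limit condition).
    alpha : float
        Activity-floor ratio E_a^L / E_a^0; default 1e-3.
    """

    n_sigma: float | None = 5.0
    alpha: float = 1e-3

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if self.n_sigma is not None and self.n_sigma <= 0:
            raise ValueError(
                f"n_sigma must be positive or None (no limit), got {self.n_sigma}"
            )


def compute_upper_bound(W, n_sigma: float) -> float:
    """``w_u = mean(|W|) + n_sigma * std(|W|)`` over all N^2 entries.

    Population (not sample) standard deviation of the absolute values.
    """
    if n_sigma is None or n_sigma <= 0:
        raise ValueError(f"n_sigma must be positive, got {n_sigma}")
    a = np.abs(np.asarray(W, dtype=float))
    return float(a.mean() + n_sigma * a.std())


def clip_weights(W, w_u: float) -> np.ndarray:
    """Clip entries with ``|w| > w_u`` to ``sign(w) * w_u``.

    Signs are preserved; no magnitude ever increases.  Idempotent.
    """
    if w_u < 0:
        raise ValueError(f"w_u must be nonnegative, got {w_u}")
    W = np.asarray(W, dtype=float)
    return np.clip(W, -w_u, w_u)


def enforce_activity_floor(W, e_a_current: float, e_a_floor: float) -> np.ndarray:
    """Rescale W by ``e_a_floor / e_a_current`` when below the floor.

    ``e_a_current`` is the node-averaged activity cost measured on a
    probe batch.  Above the floor the matrix is returned unchanged.
    An exactly zero current activity is unrecoverable by rescaling and
    raises :class:`CollapseError`.
    """
    if e_a_floor <= 0:
        raise ValueError(f"activity floor must be positive, got {e_a_floor}")
    W = np.asarray(W, dtype=float)
    if e_a_current >= e_a_floor:
        return W
    if e_a_current == 0.0:
        raise CollapseError(
            "activity cost is exactly zero; homeostatic rescaling cannot "
            "recover the network from the zero state"
        )
    return W * (e_a_floor / e_a_current)
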