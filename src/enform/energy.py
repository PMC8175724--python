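"""Network state transition and energy costs.

The network is a signed, generally asymmetric weight matrix ``W`` of shape
(N, N); ``W[i, j]`` is the connection strength from node ``j`` into node
``i``.  Activation states are N-vectors with entries in {-1, 0, +1} before
propagation and real-valued after.  Three per-node energies are defined:

* wiring cost      ``E_w(i) = sum_j |w_ij|``  — the cost of building and
  maintaining the connections of node *i*;
* activity cost    ``E_a(i) = <sum_j |v_i w_ij v_j|>_batch`` — a
  Hopfield-like signal-transfer cost evaluated on the propagated state
  ``v = W v0`` (see :func:`activity_cost` for the two supported readings
  of the partner state ``v_j``);
* normalized energy ``E_a(i) / E_w(i)`` — the objective the refinement
  loop minimizes, averaged over nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "EnergyBreakdown",
    "propagate",
    "wiring_cost",
    "activity_cost",
    "normalized_energy",
    "mean_ratio",
]

ACTIVITY_FORMS = ("post_post", "post_pre")


def _as_weight_matrix(W) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"weight matrix must be square, got shape {W.shape}")
    if not np.all(np.isfinite(W)):
        raise ValueError("weight matrix contains non-finite entries")
    return W


def _as_signal_batch(V0, n_nodes: int) -> np.ndarray:
    V0 = np.atleast_2d(np.asarray(V0, dtype=float))
    if V0.shape[1] != n_nodes:
        raise ValueError(
            f"signal dimension {V0.shape[1]} does not match network size {n_nodes}"
        )
    return V0


@dataclass(frozen=True)
class EnergyBreakdown:
    """Per-node energy costs and their ratio.

    Attributes
    ----------
    wiring : ndarray, shape (N,)
        E_w(i), nonnegative.
    activity : ndarray, shape (N,)
        E_a(i), batch-averaged, nonnegative.
    ratio : ndarray, shape (N,)
        E_a(i)/E_w(i); ``nan`` where E_w(i) == 0.
    mean_ratio : float
        Arithmetic mean of ``ratio`` over nodes with E_w(i) > 0 — the
        scalar objective of the refinement loop.
    zero_wiring : ndarray of bool, shape (N,)
        Flags nodes excluded from the mean because their wiring cost is 0.
    """

    wiring: np.ndarray
    activity: np.ndarray
    ratio: np.ndarray
    mean_ratio: float
    zero_wiring: np.ndarray


def propagate(W, V0) -> np.ndarray:
    """Single-step state transition ``v_i = sum_j w_ij v0_j``.

    Parameters
    ----------
    W : (N, N) array_like
    V0 : (B, N) or (N,) array_like

    Returns
    -------
    ndarray, shape (B, N)
    """
    W = _as_weight_matrix(W)
    V0 = _as_signal_batch(V0, W.shape[0])
    return V0 @ W.T


def wiring_cost(W) -> np.ndarray:
    """Per-node wiring cost ``E_w(i) = sum_j |w_ij|``."""
    W = _as_weight_matrix(W)
    return np.abs(W).sum(axis=1)


def activity_cost(W, V0, activity_form: str = "post_post") -> np.ndarray:
    """Per-node activity cost, averaged over the batch.

    With ``V = propagate(W, V0)`` the per-signal cost of node *i* is
    ``sum_j |V_i * w_ij * x_j|`` where the partner state ``x`` is ``V``
    (``activity_form='post_post'``, the default: both states read after
    the transition) or ``V0`` (``'post_pre'``).

    Returns the mean over the batch, so the scale is independent of the
    batch size.
    """
    if activity_form not in ACTIVITY_FORMS:
        raise ValueError(f"activity_form must be one of {ACTIVITY_FORMS}")
    W = _as_weight_matrix(W)
    V0 = _as_signal_batch(V0, W.shape[0])
    V = V0 @ W.T
    a_post = np.abs(V)
    a_partner = a_post if activity_form == "post_post" else np.abs(V0)
    # |v_i w_ij x_j| = |v_i| |w_ij| |x_j|; sum over j then mean over batch
    per_signal = a_post * (a_partner @ np.abs(W).T)  # (B, N)
    return per_signal.mean(axis=0)


def normalized_energy(W, V0, activity_form: str = "post_post") -> EnergyBreakdown:
    """Full energy breakdown, including the scalar objective.

    Nodes with zero wiring cost are excluded from ``mean_ratio`` and
    flagged (a warning is emitted); they cannot occur after random
    initialization but can after aggressive clipping.
    """
    W = _as_weight_matrix(W)
    e_w = wiring_cost(W)
    e_a = activity_cost(W, V0, activity_form=activity_form)
    zero = e_w == 0.0
    ratio = np.full_like(e_w, np.nan)
    np.divide(e_a, e_w, out=ratio, where=~zero)
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} node(s) have zero wiring cost; "
            "excluded from the mean energy ratio",
            RuntimeWarning,
            stacklevel=2,
        )
        mean = float(ratio[~zero].mean()) if (~zero).any() else 0.0
    else:
        mean = float(ratio.mean())
    return EnergyBreakdown(
        wiring=e_w, activity=e_a, ratio=ratio, mean_ratio=mean, zero_wiring=zero
    )


def mean_ratio(W, V0, activity_form: str = "post_post") -> float:
    """Scalar objective ``< E_a(i)/E_w(i) >`` over nodes with E_w > 0."""
    return normalized_energy(W, V0, activity_form=activity_form).mean_ratio
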