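"""Refinement loop: energy-ratio minimization as a Model/Results pair.

:class:`EnergyNetworkModel` holds a :class:`SimulationConfig`; ``fit()``
runs the training protocol and returns :class:`RefinementResults` with
the final and initial weight matrices, the per-epoch energy trace and
summary diagnostics.

Protocol per epoch (reference values in parentheses):

1. normalize ``W -> W / <|W|>``;
2. ``batches_per_epoch`` (10) Adam updates, each on a random sub-batch
   of ``n_signals / batches_per_epoch`` signals drawn without
   replacement from the pool of ``n_signals`` (1e4) vectors; because W
   is asymmetric, each batch update is also applied to the transposed
   matrix (objective evaluated on W^T, separate Adam state slot);
3. restore the scale with the same ``<|W|>``;
4. clip weights to ``w_u = <|w|> + n_sigma * std(|w|)`` recomputed from
   the current matrix, then rescale up if the node-averaged activity
   cost on the probe batch fell below ``alpha * E_a^0``.

The gradient of the mean energy ratio with respect to every weight is
analytic (derived by the chain rule through ``V = W V0`` and the
absolute values, with subgradient 0 at 0) and is validated against
central finite differences in the test suite.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .constraints import (
    LimitConfig,
    clip_weights,
    compute_upper_bound,
    enforce_activity_floor,
)
from .energy import ACTIVITY_FORMS, activity_cost, normalized_energy
from .signals import SIGN_SCHEMES, SignalSpec, generate_signals

__all__ = [
    "SimulationConfig",
    "EnergyNetworkModel",
    "RefinementResults",
    "NumericalError",
    "AdamState",
    "objective_gradient",
    "refine_network",
]

TRANSPOSE_MODES = ("sequential", "averaged", "off")


class NumericalError(RuntimeError):
    """Raised when a gradient or weight becomes non-finite."""


@dataclass(frozen=True)
class SimulationConfig:
    """All run parameters; defaults are the reference protocol.

    ``n_nodes=200``, ``n_epochs=200`` epochs of ``batches_per_epoch=10``
    batches over a pool of ``n_signals=1e4`` signals, Adam learning rate
    0.01, initialization N(0, 0.5^2).
    """

    n_nodes: int = 200
    n_epochs: int = 200
    batches_per_epoch: int = 10
    n_signals: int = 10_000
    learning_rate: float = 0.01
    init_mean: float = 0.0
    init_std: float = 0.5
    p_max: float = 0.5
    limit: LimitConfig = field(default_factory=LimitConfig)
    activity_form: str = "post_post"
    sign_scheme: str = "split"
    transpose_mode: str = "sequential"
    seed: int = 0

    def __post_init__(self):
        for name in ("n_nodes", "n_epochs", "batches_per_epoch", "n_signals"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.learning_rate < 0:
            raise ValueError(f"learning_rate must be >= 0, got {self.learning_rate}")
        if self.init_std <= 0:
            raise ValueError(f"init_std must be positive, got {self.init_std}")
        if self.activity_form not in ACTIVITY_FORMS:
            raise ValueError(f"activity_form must be one of {ACTIVITY_FORMS}")
        if self.sign_scheme not in SIGN_SCHEMES:
            raise ValueError(f"sign_scheme must be one of {SIGN_SCHEMES}")
        if self.transpose_mode not in TRANSPOSE_MODES:
            raise ValueError(f"transpose_mode must be one of {TRANSPOSE_MODES}")
        if self.n_signals < self.batches_per_epoch:
            raise ValueError("n_signals must be >= batches_per_epoch")

    @property
    def batch_size(self) -> int:
        return self.n_signals // self.batches_per_epoch

    def to_dict(self) -> dict:
        d = asdict(self)
        d["limit"] = {"n_sigma": self.limit.n_sigma, "alpha": self.limit.alpha}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        lim = d.pop("limit", None)
        if lim is not None and not isinstance(lim, LimitConfig):
            lim = LimitConfig(**lim)
        return cls(limit=lim if lim is not None else LimitConfig(), **d)


# ---------------------------------------------------------------------------
# objective gradient


def objective_gradient(W, V0, activity_form: str = "post_post"):
    """Analytic gradient of the mean energy ratio, and its value.

    Returns ``(G, value)`` with ``G[k, l] = d <E_a/E_w> / d w_kl``.
    Nodes with zero wiring cost are excluded from the mean (matching
    :func:`enform.energy.normalized_energy`); the subgradient of ``|x|``
    at 0 is taken as 0.
    """
    W = np.asarray(W, dtype=float)
    V0 = np.atleast_2d(np.asarray(V0, dtype=float))
    B = V0.shape[0]
    Wa = np.abs(W)
    Sw = np.sign(W)
    V = V0 @ W.T
    A = np.abs(V)
    S = np.sign(V)

    e_w = Wa.sum(axis=1)
    valid = e_w > 0.0
    n_valid = int(valid.sum())
    if n_valid == 0:
        return np.zeros_like(W), 0.0
    c = np.where(valid, 1.0, 0.0) / np.where(valid, e_w, 1.0) / n_valid

    if activity_form == "post_post":
        U = A @ Wa.T                                   # U[b,i] = sum_j |w_ij| a_bj
        e_a = (A * U).mean(axis=0)
        T = (A * c) @ Wa                               # T[b,k] = sum_i c_i a_bi |w_ik|
        grad = (c[:, None] * ((S * U).T @ V0) + (S * T).T @ V0) / B
        grad += c[:, None] * Sw * (A.T @ A) / B
    elif activity_form == "post_pre":
        A0 = np.abs(V0)
        U0 = A0 @ Wa.T
        e_a = (A * U0).mean(axis=0)
        grad = c[:, None] * ((S * U0).T @ V0) / B
        grad += c[:, None] * Sw * (A.T @ A0) / B
    else:
        raise ValueError(f"activity_form must be one of {ACTIVITY_FORMS}")

    r = np.where(valid, e_a / np.where(valid, e_w, 1.0), 0.0)
    grad -= (c * r)[:, None] * Sw
    value = float(r[valid].mean())
    return grad, value


class AdamState:
    """Minimal Adam optimizer with canonical hyperparameters
    (beta1=0.9, beta2=0.999, eps=1e-8); only the learning rate is a
    protocol parameter."""

    def __init__(self, shape, learning_rate: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = np.zeros(shape)
        self.v = np.zeros(shape)
        self.t = 0

    def update(self, x: np.ndarray, grad: np.ndarray) -> np.ndarray:
        self.t += 1
        self.m = self.beta1 * self.m + (1.0 - self.beta1) * grad
        self.v = self.beta2 * self.v + (1.0 - self.beta2) * grad * grad
        m_hat = self.m / (1.0 - self.beta1 ** self.t)
        v_hat = self.v / (1.0 - self.beta2 ** self.t)
        return x - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


@dataclass
class _OptimizerState:
    forward: AdamState
    transpose: AdamState


def initialize(config: SimulationConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Random initial matrix: i.i.d. N(init_mean, init_std^2)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return rng.normal(config.init_mean, config.init_std,
                      size=(config.n_nodes, config.n_nodes))


def epoch_step(W, pool, config: SimulationConfig, state: _OptimizerState,
               probe, e_a_floor: float | None,
               rng: np.random.Generator, epoch: int):
    """One epoch: normalize, batch updates (W and W^T), restore, constrain.

    Returns ``(W, diagnostics, state)`` where ``diagnostics`` is a dict
    with the epoch-end objective on the probe batch (``mean_ratio``),
    the applied weight bound (``w_u``, NaN when unlimited), the maximum
    |w| right after clipping (``max_abs_w_clipped``), the homeostatic
    rescale factor (``floor_rescale``, 1.0 when the floor was not hit)
    and the epoch-end probe activity cost (``e_a_probe``).
    """
    scale = float(np.abs(W).mean())
    if not np.isfinite(scale) or scale == 0.0:
        raise NumericalError(f"degenerate weight scale at epoch {epoch}")
    W = W / scale

    batch_size = config.batch_size
    order = rng.permutation(pool.shape[0])
    for b in range(config.batches_per_epoch):
        batch = pool[order[b * batch_size:(b + 1) * batch_size]]
        g, _ = objective_gradient(W, batch, config.activity_form)
        if not np.all(np.isfinite(g)):
            raise NumericalError(f"non-finite gradient at epoch {epoch}, batch {b}")
        if config.transpose_mode == "averaged":
            gt, _ = objective_gradient(W.T, batch, config.activity_form)
            W = state.forward.update(W, 0.5 * (g + gt.T))
        else:
            W = state.forward.update(W, g)
            if config.transpose_mode == "sequential":
                gt, _ = objective_gradient(W.T, batch, config.activity_form)
                W = state.transpose.update(W.T, gt).T
        if not np.all(np.isfinite(W)):
            raise NumericalError(f"non-finite weight at epoch {epoch}, batch {b}")

    W = W * scale

    w_u = float("nan")
    if config.limit.n_sigma is not None:
        w_u = compute_upper_bound(W, config.limit.n_sigma)
        W = clip_weights(W, w_u)
    max_abs_clipped = float(np.abs(W).max())

    rescale = 1.0
    e_a = float(activity_cost(W, probe, config.activity_form).mean())
    if e_a_floor is not None and e_a < e_a_floor:
        W = enforce_activity_floor(W, e_a, e_a_floor)
        rescale = e_a_floor / e_a
        e_a = float(activity_cost(W, probe, config.activity_form).mean())

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mr = normalized_energy(W, probe, config.activity_form).mean_ratio
    diag = {
        "mean_ratio": mr,
        "w_u": w_u,
        "max_abs_w_clipped": max_abs_clipped,
        "floor_rescale": rescale,
        "e_a_probe": e_a,
    }
    return W, diag, state


# ---------------------------------------------------------------------------
# Model / Results


class EnergyNetworkModel:
    """Energy-constrained network-formation model.

    Parameters
    ----------
    config : SimulationConfig, optional
        Full run specification; keyword arguments override individual
        fields (``n_sigma`` and ``alpha`` are accepted as shortcuts for
        the limit configuration).

    Examples
    --------
    >>> model = EnergyNetworkModel(n_nodes=50, n_epochs=50, seed=1)
    >>> res = model.fit()
    >>> res.trace["mean_ratio"].iloc[-1] < res.trace["mean_ratio"].iloc[0]
    True
    """

    def __init__(self, config: SimulationConfig | None = None, **kwargs):
        if config is None:
            config = SimulationConfig()
        if kwargs:
            d = config.to_dict()
            lim = d["limit"]
            for key in ("n_sigma", "alpha"):
                if key in kwargs:
                    lim[key] = kwargs.pop(key)
            d.update(kwargs)
            config = SimulationConfig.from_dict(d)
        self.config = config

    @classmethod
    def from_config_file(cls, path) -> "EnergyNetworkModel":
        """Build from a flat YAML or JSON file mirroring SimulationConfig."""
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh)
        lim = {k: d.pop(k) for k in ("n_sigma", "alpha") if k in d}
        if lim and "limit" not in d:
            d["limit"] = lim
        return cls(SimulationConfig.from_dict(d))

    def fit(self, callback=None) -> "RefinementResults":
        """Run the refinement protocol; deterministic given the seed.

        Parameters
        ----------
        callback : callable, optional
            ``callback(epoch, mean_ratio)`` after every epoch.
        """
        cfg = self.config
        ss = np.random.SeedSequence(cfg.seed)
        rng_signals, rng_init, rng_shuffle = (
            np.random.default_rng(s) for s in ss.spawn(3)
        )
        pool = generate_signals(
            SignalSpec(cfg.n_signals, cfg.n_nodes, p_max=cfg.p_max,
                       sign_scheme=cfg.sign_scheme),
            rng=rng_signals,
        ).astype(float)
        probe = pool[: cfg.batch_size]

        W0 = initialize(cfg, rng_init)
        e_a0 = float(activity_cost(W0, probe, cfg.activity_form).mean())
        e_a_floor = cfg.limit.alpha * e_a0 if e_a0 > 0 else None

        state = _OptimizerState(
            forward=AdamState(W0.shape, cfg.learning_rate),
            transpose=AdamState(W0.shape, cfg.learning_rate),
        )
        W = W0.copy()
        records = []
        from .constraints import CollapseError

        try:
            for epoch in range(cfg.n_epochs):
                W, diag, state = epoch_step(
                    W, pool, cfg, state, probe, e_a_floor, rng_shuffle, epoch
                )
                records.append(diag)
                if callback is not None:
                    callback(epoch, diag["mean_ratio"])
        except (NumericalError, CollapseError) as exc:
            raise type(exc)(
                f"{exc} (run config: N={cfg.n_nodes}, seed={cfg.seed})"
            ) from exc

        diagnostics = pd.DataFrame(records)
        diagnostics.insert(0, "epoch", np.arange(cfg.n_epochs))
        return RefinementResults(
            weights=W,
            initial_weights=W0,
            trace=diagnostics[["epoch", "mean_ratio"]].copy(),
            config=cfg,
            e_a_initial=e_a0,
            diagnostics=diagnostics,
        )


@dataclass
class RefinementResults:
    """Outcome of a refinement run.

    Attributes
    ----------
    weights : ndarray
        Final (N, N) weight matrix.
    initial_weights : ndarray
        The pre-training random matrix, kept for baseline comparisons.
    trace : pandas.DataFrame
        Columns ``epoch`` and ``mean_ratio`` (objective on the fixed
        probe batch after each epoch's constraint step).
    config : SimulationConfig
    e_a_initial : float
        Node-averaged activity cost of the initial matrix (E_a^0).
    diagnostics : pandas.DataFrame or None
        Per-epoch constraint diagnostics: the applied weight bound
        ``w_u``, ``max_abs_w_clipped`` right after clipping, the
        homeostatic ``floor_rescale`` factor and the probe activity
        cost ``e_a_probe``.
    """

    weights: np.ndarray
    initial_weights: np.ndarray
    trace: pd.DataFrame
    config: SimulationConfig
    e_a_initial: float
    diagnostics: pd.DataFrame | None = None

    def binned_trace(self, bin_size: int = 10) -> pd.DataFrame:
        """Objective averaged over consecutive ``bin_size``-epoch bins."""
        t = self.trace["mean_ratio"].to_numpy()
        n_bins = len(t) // bin_size
        binned = t[: n_bins * bin_size].reshape(n_bins, bin_size).mean(axis=1)
        return pd.DataFrame({"bin": np.arange(n_bins), "mean_ratio": binned})

    def node_strength(self) -> np.ndarray:
        from .metrics import node_strength

        return node_strength(self.weights)

    def strength_distribution(self, initial: bool = False):
        from .metrics import node_strength, strength_distribution

        W = self.initial_weights if initial else self.weights
        return strength_distribution(node_strength(W))

    def cluster_curve(self, initial: bool = False, r_step: float = 0.01):
        from .metrics import cluster_curve

        W = self.initial_weights if initial else self.weights
        return cluster_curve(W, r_step=r_step)

    def summary(self) -> str:
        cfg = self.config
        s = self.node_strength()
        mr = self.trace["mean_ratio"].to_numpy()
        n_sigma = cfg.limit.n_sigma
        lines = [
            "Energy-constrained network formation — refinement results",
            "=" * 58,
            f"nodes                 {cfg.n_nodes}",
            f"epochs x batches      {cfg.n_epochs} x {cfg.batches_per_epoch}",
            f"signal pool           {cfg.n_signals} (p_max={cfg.p_max})",
            f"weight limit n_sigma  {'none' if n_sigma is None else n_sigma}",
            f"activity floor alpha  {cfg.limit.alpha:g}",
            f"seed                  {cfg.seed}",
            "-" * 58,
            f"objective <E_a/E_w>   first epoch {mr[0]:.6g}",
            f"                      last epoch  {mr[-1]:.6g}",
            f"initial E_a^0         {self.e_a_initial:.6g}",
            f"node strength         min {s.min():.4g}  max {s.max():.4g}  "
            f"CV {s.std() / s.mean():.3f}",
        ]
        return "\n".join(lines)

    def plot_trace(self, ax=None, bin_size: int | None = None):
        """Plot the objective trace (optionally 10-epoch binned)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if bin_size:
            b = self.binned_trace(bin_size)
            ax.plot(b["bin"] * bin_size, b["mean_ratio"], marker="o")
        else:
            ax.plot(self.trace["epoch"], self.trace["mean_ratio"])
        ax.set_xlabel("epoch")
        ax.set_ylabel(r"$\langle E_a / E_w \rangle$")
        ax.set_yscale("log")
        return ax

    def save(self, run_dir) -> Path:
        """Write the run directory: final/initial matrices as header-free
        dense CSV, the trace as (epoch, mean_ratio) CSV, and a JSON
        manifest with the full configuration."""
        run_dir = Path(run_dir)
        run_dir.mkdir(parents=True, exist_ok=True)
        np.savetxt(run_dir / "final_weights.csv", self.weights, delimiter=",")
        np.savetxt(run_dir / "initial_weights.csv", self.initial_weights,
                   delimiter=",")
        self.trace.to_csv(run_dir / "energy_trace.csv", index=False)
        if self.diagnostics is not None:
            self.diagnostics.to_csv(run_dir / "diagnostics.csv", index=False)
        files = ["final_weights.csv", "initial_weights.csv",
                 "energy_trace.csv", "manifest.json"]
        if self.diagnostics is not None:
            files.append("diagnostics.csv")
        manifest = {
            "config": self.config.to_dict(),
            "e_a_initial": self.e_a_initial,
            "files": files,
        }
        with open(run_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        return run_dir

    @classmethod
    def load(cls, run_dir) -> "RefinementResults":
        run_dir = Path(run_dir)
        with open(run_dir / "manifest.json") as fh:
            manifest = json.load(fh)
        diag_path = run_dir / "diagnostics.csv"
        return cls(
            weights=np.loadtxt(run_dir / "final_weights.csv", delimiter=",",
                               ndmin=2),
            initial_weights=np.loadtxt(run_dir / "initial_weights.csv",
                                       delimiter=",", ndmin=2),
            trace=pd.read_csv(run_dir / "energy_trace.csv"),
            config=SimulationConfig.from_dict(manifest["config"]),
            e_a_initial=manifest["e_a_initial"],
            diagnostics=pd.read_csv(diag_path) if diag_path.exists() else None,
        )


def refine_network(config: SimulationConfig | None = None, **kwargs) -> RefinementResults:
    """Convenience wrapper: build the model and fit it."""
    return EnergyNetworkModel(config, **kwargs).fit()
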