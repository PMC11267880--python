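"""Training orchestration: runs, metrics, multi-seed protocol, sweeps.

A run pairs a clean and a noisy forward pass per training sequence, feeds
the per-timestep loss differences to the configured learning rule, applies
the updates, and records train/test loss (clean passes only — evaluation is
always noise-free) each epoch.  The decorrelation matrix, when enabled,
learns in parallel with the forward weights from the clean pass activity.

Instability — a hallmark failure mode of perturbation rules at scale — is
detected (non-finite or threshold-exceeding loss or weights), never masked:
an unstable run stops early and is flagged, and sweep summaries average
over the stable runs only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import rules as R
from .model import (
    RNNParams,
    forward_clean,
    forward_noisy_node,
    forward_noisy_weight,
    init_params,
    loss_record,
    sequence_loss,
)
from .rules import AdamState, RuleConfig, UpdateSet
from .tasks import SequenceDataset

__all__ = [
    "RunConfig",
    "RunHistory",
    "train_model",
    "run_experiment",
    "aggregate_histories",
    "final_performance",
    "decorrelation_loss",
    "scalability_sweep",
    "detect_instability",
]

_NODE_RULES = {"np_local": R.np_update_local, "np_global": R.np_update_global,
               "anp": R.anp_update}
_WEIGHT_RULES = {"wp_local": R.wp_update_local, "wp_global": R.wp_update_global}
_LOCAL_RULES = ("np_local", "anp", "wp_local")


@dataclass
class RunConfig:
    """Everything needed to reproduce one training experiment."""

    train_data: SequenceDataset
    test_data: SequenceDataset
    hidden_dim: int = 64
    rule: RuleConfig = field(default_factory=RuleConfig)
    eta: float = 1e-4
    epsilon: float = 1e-5
    epochs: int = 100
    seeds: Sequence[int] = (1, 2, 3, 4, 5)
    decorrelate: bool = False
    loss_threshold: float = 1e6
    weight_bound: float = 1e6
    update_cadence: str = "sequence"  # or "online"

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be at least 1")
        if len(self.seeds) == 0:
            raise ValueError("at least one seed is required")
        if self.update_cadence not in ("sequence", "online"):
            raise ValueError(f"unknown update cadence {self.update_cadence!r}")
        if self.update_cadence == "online" and self.rule.rule_name not in _LOCAL_RULES:
            raise ValueError(
                "online updates require a per-timestep rule "
                f"({', '.join(_LOCAL_RULES)}), not {self.rule.rule_name!r}"
            )


@dataclass
class RunHistory:
    """Per-epoch loss curves and the outcome of one seeded run."""

    train_loss: List[float]
    test_loss: List[float]
    decorr_loss: List[float]
    stable: bool
    params: RNNParams
    seed: int
    rule_name: str

    @property
    def epochs_completed(self) -> int:
        return len(self.train_loss)

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "epoch": np.arange(self.epochs_completed),
            "train_loss": self.train_loss,
            "test_loss": self.test_loss,
        }
        if self.decorr_loss:
            cols["decorrelation_loss"] = self.decorr_loss
        return pd.DataFrame(cols)

    def summary(self, window: int = 50) -> dict:
        out = {
            "seed": self.seed,
            "rule": self.rule_name,
            "stable": self.stable,
            "epochs_completed": self.epochs_completed,
        }
        if self.stable and self.epochs_completed >= window:
            out["final_train"] = float(np.mean(self.train_loss[-window:]))
            out["final_test"] = float(np.mean(self.test_loss[-window:]))
        return out


def detect_instability(
    loss_value: float,
    params: Optional[RNNParams] = None,
    loss_threshold: float = 1e6,
    weight_bound: float = 1e6,
) -> bool:
    """True iff the loss is non-finite / above threshold or weights exploded."""
    if not np.isfinite(loss_value) or loss_value > loss_threshold:
        return True
    if params is not None:
        mats = [params.A, params.R, params.B]
        if params.D is not None:
            mats.append(params.D)
        for m in mats:
            if not np.all(np.isfinite(m)) or np.max(np.abs(m)) > weight_bound:
                return True
    return False


def _mean_clean_loss(params: RNNParams, ds: SequenceDataset) -> float:
    losses = []
    for u, y_star in zip(ds.inputs, ds.targets):
        traj = forward_clean(params, u)
        losses.append(sequence_loss(traj.y, y_star).L)
    return float(np.mean(losses))


def decorrelation_loss(x_star_sequences) -> float:
    """Mean squared strictly-lower-triangular entry of the covariance of x*.

    ``x_star_sequences`` is one (n, H) array or a list of (T, H) arrays,
    pooled over timesteps before the empirical covariance is taken.
    """
    if isinstance(x_star_sequences, np.ndarray):
        X = np.atleast_2d(x_star_sequences)
    else:
        X = np.concatenate([np.atleast_2d(x) for x in x_star_sequences], axis=0)
    if X.shape[1] < 2:
        raise ValueError("decorrelation loss needs at least 2 hidden units")
    cov = np.cov(X.T)
    lower = cov[np.tril_indices_from(cov, k=-1)]
    return float(np.mean(lower**2))


def _decorr_loss_on(params: RNNParams, ds: SequenceDataset) -> float:
    stars = [forward_clean(params, u).x_star for u in ds.inputs]
    return decorrelation_loss(stars)


def _sequence_step(
    params: RNNParams,
    u: np.ndarray,
    y_star: np.ndarray,
    cfg: RunConfig,
    rng: np.random.Generator,
    adam: Optional[AdamState],
) -> RNNParams:
    """One training sequence at sequence cadence: accumulate, apply once."""
    rule = cfg.rule.rule_name
    clean = forward_clean(params, u)
    if rule == "bp":
        updates = R.bptt_gradient(params, u, y_star, clean=clean)
    else:
        if rule in _NODE_RULES:
            noisy = forward_noisy_node(params, u, sigma=cfg.rule.sigma, rng=rng)
            fn = _NODE_RULES[rule]
        else:
            noisy = forward_noisy_weight(params, u, sigma=cfg.rule.sigma, rng=rng)
            fn = _WEIGHT_RULES[rule]
        losses = loss_record(clean, noisy, y_star)
        updates = fn(clean, noisy, losses, cfg.rule)
    if cfg.decorrelate:
        updates.dD = R.decorrelation_update(clean.x_star, params.D)
    return R.apply_updates(params, updates, cfg.eta, cfg.epsilon, adam)


def _online_step(
    params: RNNParams,
    u: np.ndarray,
    y_star: np.ndarray,
    cfg: RunConfig,
    rng: np.random.Generator,
) -> RNNParams:
    """One training sequence with updates applied at every timestep.

    Clean and noisy states propagate through the (slowly changing) weights;
    each step's update uses only that step's loss difference and noise, so
    the rule is fully online.
    """
    rc = cfg.rule
    rule = rc.rule_name
    sigma = rc.sigma
    H = params.hidden_dim
    O = params.output_dim
    decorrelated = params.D is not None
    x_prev = np.zeros(H) if not decorrelated else params.D @ np.zeros(H)
    xn_prev = x_prev.copy()
    N = rc.N if rc.N is not None else H + O

    for t in range(u.shape[0]):
        alpha = params.A @ u[t] + params.R @ x_prev
        x = np.tanh(alpha)
        state = params.D @ x if decorrelated else x
        y = params.B @ state
        if rule == "wp_local":
            xiW = rng.normal(0, sigma, size=params.A.shape)
            nuW = rng.normal(0, sigma, size=params.R.shape)
            zeW = rng.normal(0, sigma, size=params.B.shape)
            alpha_n = (params.A + xiW) @ u[t] + (params.R + nuW) @ xn_prev
            xn = np.tanh(alpha_n)
            state_n = params.D @ xn if decorrelated else xn
            yn = (params.B + zeW) @ state_n
        else:
            xi = rng.normal(0, sigma, size=H)
            nu = rng.normal(0, sigma, size=O)
            alpha_n = params.A @ u[t] + params.R @ xn_prev + xi
            xn = np.tanh(alpha_n)
            state_n = params.D @ xn if decorrelated else xn
            yn = params.B @ state_n + nu
        d_ell = np.sum((yn - y_star[t]) ** 2) - np.sum((y - y_star[t]) ** 2)

        if rule == "np_local":
            w = d_ell / sigma**2
            upd = UpdateSet(
                dA=w * np.outer(xi, u[t]),
                dB=w * np.outer(nu, state),
                dR=w * np.outer(xi, x_prev),
            )
        elif rule == "anp":
            d_alpha = alpha_n - alpha
            d_beta = yn - y  # output layer is linear: beta == y
            na = float(d_alpha @ d_alpha)
            nb = float(d_beta @ d_beta)
            if rc.anp_normalization == "joint":
                nt = na + nb
                wa = wb = d_ell / nt if nt > R.ANP_NORM_TOL else 0.0
            else:
                wa = d_ell / na if na > R.ANP_NORM_TOL else 0.0
                wb = d_ell / nb if nb > R.ANP_NORM_TOL else 0.0
            upd = UpdateSet(
                dA=N * wa * np.outer(d_alpha, u[t]),
                dB=N * wb * np.outer(d_beta, state),
                dR=N * wa * np.outer(d_alpha, x_prev),
            )
        else:  # wp_local
            w = d_ell / sigma**2
            upd = UpdateSet(dA=w * xiW, dB=w * zeW, dR=w * nuW)
        if cfg.decorrelate:
            upd.dD = R.decorrelation_update(state[None, :], params.D)
        params = R.apply_updates(params, upd, cfg.eta, cfg.epsilon)
        if detect_instability(0.0, params, cfg.loss_threshold, cfg.weight_bound):
            break  # stop before non-finite weights propagate
        x_prev = state
        xn_prev = state_n
    return params


def train_model(cfg: RunConfig, seed: Optional[int] = None) -> RunHistory:
    """Run one seeded training experiment and return its history.

    Instability aborts the run: the history keeps the epochs completed so
    far and carries ``stable=False``.
    """
    seed = int(cfg.seeds[0] if seed is None else seed)
    ss = np.random.SeedSequence(seed)
    init_rng, noise_rng, order_rng = (np.random.default_rng(s) for s in ss.spawn(3))
    ds = cfg.train_data
    params = init_params(
        ds.input_dim, cfg.hidden_dim, ds.output_dim,
        decorrelate=cfg.decorrelate, rng=init_rng,
    )
    if cfg.rule.rule_name != "bp" and cfg.rule.N is None:
        cfg = replace(cfg, rule=replace(cfg.rule, N=cfg.hidden_dim + ds.output_dim))
    adam = AdamState() if cfg.rule.rule_name == "bp" else None
    order = order_rng.permutation(len(ds))  # fixed seeded visiting order

    train_curve: List[float] = []
    test_curve: List[float] = []
    decorr_curve: List[float] = []
    stable = True
    for _epoch in range(cfg.epochs):
        for i in order:
            if cfg.update_cadence == "online":
                params = _online_step(params, ds.inputs[i], ds.targets[i], cfg, noise_rng)
            else:
                params = _sequence_step(
                    params, ds.inputs[i], ds.targets[i], cfg, noise_rng, adam
                )
            if detect_instability(0.0, params, cfg.loss_threshold, cfg.weight_bound):
                stable = False
                break
        if stable:
            tr = _mean_clean_loss(params, cfg.train_data)
            te = _mean_clean_loss(params, cfg.test_data)
            if detect_instability(tr, params, cfg.loss_threshold, cfg.weight_bound) or \
               detect_instability(te, None, cfg.loss_threshold):
                stable = False
            else:
                train_curve.append(tr)
                test_curve.append(te)
                if cfg.decorrelate:
                    decorr_curve.append(_decorr_loss_on(params, cfg.train_data))
        if not stable:
            break
    return RunHistory(
        train_loss=train_curve, test_loss=test_curve, decorr_loss=decorr_curve,
        stable=stable, params=params, seed=seed, rule_name=cfg.rule.rule_name,
    )


def run_experiment(cfg: RunConfig) -> List[RunHistory]:
    """The multi-seed protocol: one run per seed in ``cfg.seeds``."""
    return [train_model(cfg, seed=s) for s in cfg.seeds]


def aggregate_histories(histories: List[RunHistory]) -> pd.DataFrame:
    """Per-epoch mean with min/max bands over the seeds, stable runs only."""
    stable = [h for h in histories if h.stable]
    if not stable:
        return pd.DataFrame(
            columns=["epoch", "train_mean", "train_min", "train_max",
                     "test_mean", "test_min", "test_max"]
        )
    n_epochs = min(h.epochs_completed for h in stable)
    tr = np.array([h.train_loss[:n_epochs] for h in stable])
    te = np.array([h.test_loss[:n_epochs] for h in stable])
    return pd.DataFrame({
        "epoch": np.arange(n_epochs),
        "train_mean": tr.mean(axis=0), "train_min": tr.min(axis=0),
        "train_max": tr.max(axis=0),
        "test_mean": te.mean(axis=0), "test_min": te.min(axis=0),
        "test_max": te.max(axis=0),
    })


def final_performance(history: RunHistory, window: int = 50) -> float:
    """Summary metric: mean test loss over the last ``window`` epochs."""
    if history.epochs_completed < window:
        raise ValueError(
            f"history has {history.epochs_completed} epochs, need >= {window}"
        )
    return float(np.mean(history.test_loss[-window:]))


def scalability_sweep(
    cfg: RunConfig,
    hidden_sizes: Sequence[int],
    rule_names: Optional[Sequence[str]] = None,
    run_fn: Optional[Callable[[RunConfig, int], RunHistory]] = None,
    window: int = 50,
) -> pd.DataFrame:
    """Final performance vs. network size, per rule, over the seed protocol.

    Each (size, rule) cell runs every seed; the cell reports the number of
    stable runs and the mean final train/test loss over the *stable* runs
    only.  A cell whose runs were all unstable reports NaN means (an empty
    data point).  ``run_fn`` may replace the real trainer, e.g. for
    protocol tests.
    """
    if len(hidden_sizes) == 0:
        raise ValueError("hidden_sizes must be non-empty")
    rule_names = list(rule_names or [cfg.rule.rule_name])
    run_fn = run_fn or (lambda c, s: train_model(c, seed=s))
    rows = []
    for size in hidden_sizes:
        for rule in rule_names:
            cell_cfg = replace(
                cfg, hidden_dim=size, rule=replace(cfg.rule, rule_name=rule)
            )
            finals_tr, finals_te, n_stable = [], [], 0
            for s in cfg.seeds:
                h = run_fn(cell_cfg, int(s))
                if h.stable and h.epochs_completed >= window:
                    n_stable += 1
                    finals_tr.append(np.mean(h.train_loss[-window:]))
                    finals_te.append(np.mean(h.test_loss[-window:]))
            rows.append({
                "hidden": int(size), "rule": rule, "n_seeds": len(cfg.seeds),
                "stable_count": n_stable,
                "mean_final_train": float(np.mean(finals_tr)) if finals_tr else np.nan,
                "mean_final_test": float(np.mean(finals_te)) if finals_te else np.nan,
            })
    return pd.DataFrame(rows)
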