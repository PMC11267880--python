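"""Learning rules: perturbation-based updates, exact BPTT, and decorrelation.

All perturbation rules consume a (clean, noisy) pair of forward passes over
the same input sequence and turn per-timestep loss changes into weight
updates via eligibility traces — products of the injected perturbation (or
the measured activity difference) with the presynaptic activity:

* ``np_update_local``  — node perturbation with the per-timestep reinforcement
  signal delta_ell_t = ell~_t - ell_t:
  dW = sigma^-2 sum_t delta_ell_t * noise_t * presyn_t^T.
* ``np_update_global`` — conventional variant using the single per-sequence
  signal delta_L = L~ - L outside the sum.
* ``anp_update``       — activity-based node perturbation: replaces the raw
  noise with the measured pre-activation difference, normalized by its
  squared magnitude, scaled by the total neuron count N.  This approximates
  a directional derivative and aligns more closely with the true gradient.
* ``wp_update_local`` / ``wp_update_global`` — weight perturbation; the noise
  already has weight shape, so no presynaptic factor appears.
* ``bptt_gradient``    — the exact gradient of the sequence loss, computed by
  reverse-mode accumulation through the unrolled recurrence (the baseline
  the stochastic rules approximate).
* ``decorrelation_update`` — anti-Hebbian update of the decorrelation matrix,
  dD = sum_t (x*_t x*_t^T - diag(x*_t^2)) D, applied as D <- D - eps*dD.

Updates are applied as W <- W - eta*dW (plain SGD); the BPTT baseline may
route its gradient through Adam moment estimates instead.

The update equations as usually written pair dA with x_t^T and dB with
u_t^T; that contradicts the network wiring (A reads u_t, B reads x_t) and is
only shape-consistent for square nets.  The default
``presynaptic_convention='corrected'`` uses the wiring-consistent pairing;
``'as_printed'`` keeps the literal one for auditability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import (
    LossRecord,
    NoisyTrajectory,
    RNNParams,
    ShapeError,
    Trajectory,
)

__all__ = [
    "UpdateSet",
    "RuleConfig",
    "AdamState",
    "np_update_local",
    "np_update_global",
    "anp_update",
    "wp_update_local",
    "wp_update_global",
    "bptt_gradient",
    "decorrelation_update",
    "apply_updates",
    "RULE_NAMES",
]

RULE_NAMES = ("np_local", "np_global", "anp", "wp_local", "wp_global", "bp")

# timesteps whose squared activity difference is below this contribute
# nothing to ANP updates (division guard)
ANP_NORM_TOL = 1e-12


@dataclass
class UpdateSet:
    """Candidate weight changes produced by one rule on one sequence."""

    dA: np.ndarray
    dB: np.ndarray
    dR: np.ndarray
    dD: Optional[np.ndarray] = None

    def flat(self) -> np.ndarray:
        """Forward-weight updates as one vector (dD excluded)."""
        return np.concatenate([self.dA.ravel(), self.dB.ravel(), self.dR.ravel()])

    def is_finite(self) -> bool:
        parts = [self.dA, self.dB, self.dR]
        if self.dD is not None:
            parts.append(self.dD)
        return all(np.all(np.isfinite(p)) for p in parts)

    @staticmethod
    def zeros_like(params: RNNParams) -> "UpdateSet":
        return UpdateSet(
            dA=np.zeros_like(params.A),
            dB=np.zeros_like(params.B),
            dR=np.zeros_like(params.R),
            dD=None if params.D is None else np.zeros_like(params.D),
        )


@dataclass
class RuleConfig:
    """Which rule to run and how.

    Parameters
    ----------
    rule_name : one of np_local, np_global, anp, wp_local, wp_global, bp.
    sigma : perturbation standard deviation (ignored by bp).
    anp_uses_delta_loss : ANP reinforcement signal is delta_ell_t when True
        (default), the literal per-step loss ell_t when False.  With ell_t
        always nonnegative the literal form cannot distinguish improvement
        from worsening, hence the default.
    presynaptic_convention : 'corrected' (wiring-consistent, default) or
        'as_printed'.
    anp_normalization : 'joint' (default) divides by the whole-network
        pre-activation difference norm ||delta_alpha_t||^2 +
        ||delta_beta_t||^2, which together with the N scaling makes the
        update an unbiased directional-derivative estimate of the gradient
        and keeps its variance below NP's; 'per_layer' divides each layer's
        difference by its own norm.
    N : neuron count used by the ANP scaling; inferred from the trajectory
        shapes (hidden + output units) when None.
    """

    rule_name: str = "anp"
    sigma: float = 1e-3
    anp_uses_delta_loss: bool = True
    presynaptic_convention: str = "corrected"
    anp_normalization: str = "joint"
    N: Optional[int] = None

    def __post_init__(self) -> None:
        if self.rule_name not in RULE_NAMES:
            raise ValueError(f"unknown rule {self.rule_name!r}; choose from {RULE_NAMES}")
        if self.presynaptic_convention not in ("corrected", "as_printed"):
            raise ValueError(
                f"unknown presynaptic convention {self.presynaptic_convention!r}"
            )
        if self.anp_normalization not in ("joint", "per_layer"):
            raise ValueError(f"unknown ANP normalization {self.anp_normalization!r}")
        if self.rule_name != "bp" and self.sigma <= 0:
            raise ValueError(
                f"sigma must be positive for {self.rule_name}, got {self.sigma}"
            )


def _check_pair(clean: Trajectory, noisy: NoisyTrajectory) -> None:
    if clean.T != noisy.T:
        raise ShapeError(f"clean pass has T={clean.T}, noisy pass T={noisy.T}")


def _presyn(clean: Trajectory, x0: Optional[np.ndarray]):
    """(input, readout-presynaptic, recurrent-presynaptic) arrays, all (T, .)."""
    if x0 is None:
        x0 = np.zeros(clean.x.shape[1])
    return clean.u, clean.readout_states(), clean.presynaptic_hidden(x0)


def _paired_traces(
    sig_h: np.ndarray,
    sig_o: np.ndarray,
    clean: Trajectory,
    cfg: RuleConfig,
    x0: Optional[np.ndarray],
):
    """Eligibility-trace sums sum_t sig_t presyn_t^T for node-level signals.

    ``sig_h`` (T, hidden) and ``sig_o`` (T, output) carry the reinforcement
    weighting already folded in.
    """
    u, s_read, s_rec = _presyn(clean, x0)
    if cfg.presynaptic_convention == "corrected":
        pre_A, pre_B = u, s_read
    else:  # literal pairing: dA with x_t^T, dB with u_t^T
        pre_A, pre_B = s_read, u
    dA = sig_h.T @ pre_A
    dB = sig_o.T @ pre_B
    dR = sig_h.T @ s_rec
    return dA, dB, dR


def _require_node_noise(noisy: NoisyTrajectory, rule: str) -> dict:
    if noisy.node_noise is None:
        raise ValueError(f"{rule} requires a node-noise trajectory")
    return noisy.node_noise


def _require_weight_noise(noisy: NoisyTrajectory, rule: str) -> dict:
    if noisy.weight_noise is None:
        raise ValueError(f"{rule} requires a weight-noise trajectory")
    return noisy.weight_noise


def np_update_local(
    clean: Trajectory,
    noisy: NoisyTrajectory,
    losses: LossRecord,
    cfg: RuleConfig,
    x0: Optional[np.ndarray] = None,
) -> UpdateSet:
    """Node perturbation with per-timestep reinforcement signals delta_ell_t."""
    _check_pair(clean, noisy)
    noise = _require_node_noise(noisy, "np_update_local")
    w = losses.delta_ell / cfg.sigma**2
    dA, dB, dR = _paired_traces(
        noise["xi"] * w[:, None], noise["nu"] * w[:, None], clean, cfg, x0
    )
    return UpdateSet(dA=dA, dB=dB, dR=dR)


def np_update_global(
    clean: Trajectory,
    noisy: NoisyTrajectory,
    losses: LossRecord,
    cfg: RuleConfig,
    x0: Optional[np.ndarray] = None,
) -> UpdateSet:
    """Node perturbation with the single per-sequence signal delta_L."""
    _check_pair(clean, noisy)
    noise = _require_node_noise(noisy, "np_update_global")
    w = losses.delta_L / cfg.sigma**2
    dA, dB, dR = _paired_traces(noise["xi"] * w, noise["nu"] * w, clean, cfg, x0)
    return UpdateSet(dA=dA, dB=dB, dR=dR)


def anp_update(
    clean: Trajectory,
    noisy: NoisyTrajectory,
    losses: LossRecord,
    cfg: RuleConfig,
    x0: Optional[np.ndarray] = None,
) -> UpdateSet:
    """Activity-based node perturbation through time.

    Uses the measured pre-activation differences delta_alpha_t, delta_beta_t
    between the clean and noisy passes, normalized by their squared norms,
    in place of the raw noise; scaled by the total neuron count N.  Timesteps
    with vanishing activity difference contribute zero.
    """
    _check_pair(clean, noisy)
    _require_node_noise(noisy, "anp_update")
    N = cfg.N if cfg.N is not None else clean.x.shape[1] + clean.y.shape[1]
    signal = losses.delta_ell if cfg.anp_uses_delta_loss else losses.ell

    d_alpha = noisy.alpha - clean.alpha
    d_beta = noisy.beta - clean.beta
    na = np.sum(d_alpha**2, axis=1)
    nb = np.sum(d_beta**2, axis=1)
    if cfg.anp_normalization == "joint":
        nt = na + nb
        wa = wb = np.where(nt > ANP_NORM_TOL, signal / np.maximum(nt, ANP_NORM_TOL), 0.0)
    else:
        wa = np.where(na > ANP_NORM_TOL, signal / np.maximum(na, ANP_NORM_TOL), 0.0)
        wb = np.where(nb > ANP_NORM_TOL, signal / np.maximum(nb, ANP_NORM_TOL), 0.0)
    dA, dB, dR = _paired_traces(
        d_alpha * wa[:, None], d_beta * wb[:, None], clean, cfg, x0
    )
    return UpdateSet(dA=N * dA, dB=N * dB, dR=N * dR)


def wp_update_local(
    clean: Trajectory,
    noisy: NoisyTrajectory,
    losses: LossRecord,
    cfg: RuleConfig,
    x0: Optional[np.ndarray] = None,
) -> UpdateSet:
    """Weight perturbation with per-timestep reinforcement signals."""
    _check_pair(clean, noisy)
    noise = _require_weight_noise(noisy, "wp_update_local")
    w = losses.delta_ell / cfg.sigma**2
    return UpdateSet(
        dA=np.einsum("t,t...->...", w, noise["xi"]),
        dB=np.einsum("t,t...->...", w, noise["zeta"]),
        dR=np.einsum("t,t...->...", w, noise["nu"]),
    )


def wp_update_global(
    clean: Trajectory,
    noisy: NoisyTrajectory,
    losses: LossRecord,
    cfg: RuleConfig,
    x0: Optional[np.ndarray] = None,
) -> UpdateSet:
    """Weight perturbation with the per-sequence signal delta_L.

    The noise term is read as the per-sequence sum over t of the
    per-timestep weight noise, by symmetry with the node-level rule.
    """
    _check_pair(clean, noisy)
    noise = _require_weight_noise(noisy, "wp_update_global")
    w = losses.delta_L / cfg.sigma**2
    return UpdateSet(
        dA=w * noise["xi"].sum(axis=0),
        dB=w * noise["zeta"].sum(axis=0),
        dR=w * noise["nu"].sum(axis=0),
    )


def bptt_gradient(
    params: RNNParams,
    u: np.ndarray,
    y_star: np.ndarray,
    x0: Optional[np.ndarray] = None,
    clean: Optional[Trajectory] = None,
) -> UpdateSet:
    """Exact gradient of L = (1/T) sum_t ||y_t - y*_t||^2 w.r.t. A, B, R.

    Reverse-mode accumulation through the unrolled recurrence.  When the
    network carries a decorrelation matrix D, the gradient flows through D
    but D itself is treated as fixed — it learns only via the decorrelation
    rule — so ``dD`` is returned as zero.
    """
    from .model import forward_clean  # local import to avoid cycle at module load

    if clean is None:
        clean = forward_clean(params, u, x0)
    u = clean.u
    y_star = np.atleast_2d(np.asarray(y_star, dtype=float))
    if y_star.shape != clean.y.shape:
        raise ShapeError(f"targets {y_star.shape} do not match outputs {clean.y.shape}")
    T = clean.T
    if x0 is None:
        x0 = np.zeros(params.hidden_dim)
    decorrelated = params.D is not None

    g_y = (2.0 / T) * (clean.y - y_star)          # (T, output)
    readout = clean.readout_states()              # x_t or x*_t
    presyn = clean.presynaptic_hidden(x0)         # x_{t-1} or x*_{t-1}

    dA = np.zeros_like(params.A)
    dB = g_y.T @ readout
    dR = np.zeros_like(params.R)
    g_alpha_next = np.zeros(params.hidden_dim)
    for t in range(T - 1, -1, -1):
        # gradient w.r.t. the state that feeds both readout (at t) and
        # recurrence (at t+1); in the decorrelated net that state is x*_t
        g_state = params.B.T @ g_y[t] + params.R.T @ g_alpha_next
        g_x = params.D.T @ g_state if decorrelated else g_state
        g_alpha = g_x * (1.0 - clean.x[t] ** 2)
        dA += np.outer(g_alpha, u[t])
        dR += np.outer(g_alpha, presyn[t])
        g_alpha_next = g_alpha
    return UpdateSet(
        dA=dA, dB=dB, dR=dR,
        dD=None if not decorrelated else np.zeros_like(params.D),
    )


def decorrelation_update(x_star: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Anti-Hebbian decorrelation update, summed over the sequence.

    dD = sum_t (x*_t (x*_t)^T - diag((x*_t)^2)) D — the off-diagonal part of
    the activity outer products, pushed through D.  Applied as D <- D - eps*dD,
    it shrinks cross-correlations between hidden units and has the zero
    matrix as its expectation exactly when the covariance of x* is diagonal.
    """
    if D is None:
        raise ValueError("decorrelation requires the decorrelation matrix D")
    x_star = np.atleast_2d(np.asarray(x_star, dtype=float))
    C = x_star.T @ x_star
    np.fill_diagonal(C, 0.0)
    return C @ D


@dataclass
class AdamState:
    """First/second moment estimates for the Adam-driven BPTT baseline."""

    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    step: int = 0
    m: dict = field(default_factory=dict)
    v: dict = field(default_factory=dict)

    def direction(self, name: str, g: np.ndarray) -> np.ndarray:
        """Bias-corrected Adam step direction for one parameter block."""
        if name not in self.m:
            self.m[name] = np.zeros_like(g)
            self.v[name] = np.zeros_like(g)
        self.m[name] = self.beta1 * self.m[name] + (1 - self.beta1) * g
        self.v[name] = self.beta2 * self.v[name] + (1 - self.beta2) * g**2
        m_hat = self.m[name] / (1 - self.beta1**self.step)
        v_hat = self.v[name] / (1 - self.beta2**self.step)
        return m_hat / (np.sqrt(v_hat) + self.eps)


def apply_updates(
    params: RNNParams,
    updates: UpdateSet,
    eta: float,
    epsilon: float = 0.0,
    optimizer_state: Optional[AdamState] = None,
) -> RNNParams:
    """Apply W <- W - eta*dW (and D <- D - eps*dD) and return new parameters.

    Plain SGD unless ``optimizer_state`` is given, in which case the
    forward-weight updates are routed through Adam (used for the BPTT
    baseline only).  D is always updated by plain SGD with ``epsilon``.
    """
    if eta < 0 or epsilon < 0:
        raise ValueError("learning rates must be nonnegative")
    out = params.copy()
    if optimizer_state is not None:
        optimizer_state.step += 1
        out.A -= eta * optimizer_state.direction("A", updates.dA)
        out.B -= eta * optimizer_state.direction("B", updates.dB)
        out.R -= eta * optimizer_state.direction("R", updates.dR)
    else:
        out.A -= eta * updates.dA
        out.B -= eta * updates.dB
        out.R -= eta * updates.dR
    if out.D is not None and updates.dD is not None:
        out.D -= epsilon * updates.dD
    return out
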