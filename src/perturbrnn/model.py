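"""Recurrent network model: parameters, forward passes and the sequence loss.

The network is a single-hidden-layer RNN

    x_t = tanh(A u_t + R x_{t-1}),    y_t = B x_t,

with input weights ``A`` (hidden x input), recurrent weights ``R``
(hidden x hidden) and linear readout ``B`` (output x hidden).  An optional
decorrelation matrix ``D`` (hidden x hidden) inserts a learned linear
transform after the nonlinearity,

    x*_t = D x_t,    x_t = tanh(A u_t + R x*_{t-1}),    y_t = B x*_t,

so that both the recurrence and the readout consume the decorrelated state.
Perturbation-based learning needs a second, noisy forward pass; the noisy
pass propagates its *own* recurrent state and records the exact noise draws
so learning rules can form eligibility traces from them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "RNNParams",
    "Trajectory",
    "NoisyTrajectory",
    "LossRecord",
    "init_params",
    "forward_clean",
    "forward_clean_decorrelated",
    "forward_noisy_node",
    "forward_noisy_weight",
    "sequence_loss",
    "loss_record",
    "save_params",
    "load_params",
]


class ShapeError(ValueError):
    """Raised when parameter or sequence shapes are mutually inconsistent."""


class ConfigurationError(ValueError):
    """Raised when an operation is invoked on an incompatible configuration."""


@dataclass
class RNNParams:
    """Learnable weights of the network.

    Attributes
    ----------
    A : (hidden, input) input weights
    R : (hidden, hidden) recurrent weights
    B : (output, hidden) readout weights
    D : optional (hidden, hidden) decorrelation matrix; ``None`` when the
        decorrelation mechanism is disabled.
    """

    A: np.ndarray
    R: np.ndarray
    B: np.ndarray
    D: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        if self.D is not None:
            self.D = np.asarray(self.D, dtype=float)
        self.validate()

    @property
    def input_dim(self) -> int:
        return self.A.shape[1]

    @property
    def hidden_dim(self) -> int:
        return self.A.shape[0]

    @property
    def output_dim(self) -> int:
        return self.B.shape[0]

    @property
    def n_neurons(self) -> int:
        """Total neuron count (hidden plus output), used by ANP scaling."""
        return self.hidden_dim + self.output_dim

    def validate(self) -> None:
        h = self.A.shape[0]
        if self.R.shape != (h, h):
            raise ShapeError(f"R has shape {self.R.shape}, expected {(h, h)}")
        if self.B.ndim != 2 or self.B.shape[1] != h:
            raise ShapeError(f"B has shape {self.B.shape}, expected (*, {h})")
        if self.D is not None and self.D.shape != (h, h):
            raise ShapeError(f"D has shape {self.D.shape}, expected {(h, h)}")
        for name in ("A", "R", "B", "D"):
            m = getattr(self, name)
            if m is not None and not np.all(np.isfinite(m)):
                raise ShapeError(f"{name} contains non-finite entries")

    def copy(self) -> "RNNParams":
        return RNNParams(
            self.A.copy(),
            self.R.copy(),
            self.B.copy(),
            None if self.D is None else self.D.copy(),
        )


@dataclass
class Trajectory:
    """Per-timestep record of a clean forward pass (t = 1..T, stored 0-based)."""

    u: np.ndarray        # (T, input_dim)
    alpha: np.ndarray    # (T, hidden) pre-activations
    x: np.ndarray        # (T, hidden) hidden states tanh(alpha)
    beta: np.ndarray     # (T, output) output pre-activations
    y: np.ndarray        # (T, output) outputs (= beta, linear readout)
    x_star: Optional[np.ndarray] = None  # (T, hidden), present iff D is used
    pre0: Optional[np.ndarray] = None    # state fed to R at t=1 (x0 or D x0)

    @property
    def T(self) -> int:
        return self.u.shape[0]

    def presynaptic_hidden(self, x0: Optional[np.ndarray] = None) -> np.ndarray:
        """States feeding R at each step: x_{t-1} (or x*_{t-1}).

        Returns a (T, hidden) array whose row t is the state the recurrence
        consumed when producing x_t.  The first row is the recorded initial
        presynaptic state (falling back to ``x0`` for hand-built records).
        """
        states = self.x if self.x_star is None else self.x_star
        first = self.pre0 if self.pre0 is not None else x0
        if first is None:
            first = np.zeros(states.shape[1])
        return np.vstack([first[None, :], states[:-1]])

    def readout_states(self) -> np.ndarray:
        """States feeding B at each step: x_t, or x*_t in a decorrelated net."""
        return self.x if self.x_star is None else self.x_star


@dataclass
class NoisyTrajectory(Trajectory):
    """Perturbed forward pass plus the exact noise realizations injected.

    Exactly one of ``node_noise`` / ``weight_noise`` is populated.
    """

    node_noise: Optional[dict] = None    # {"xi": (T, hidden), "nu": (T, output)}
    weight_noise: Optional[dict] = None  # {"xi": (T,)+A.shape, "nu": (T,)+R.shape,
                                         #  "zeta": (T,)+B.shape}

    def __post_init__(self) -> None:
        if (self.node_noise is None) == (self.weight_noise is None):
            raise ConfigurationError(
                "exactly one of node_noise / weight_noise must be populated"
            )


@dataclass
class LossRecord:
    """Per-timestep losses of a clean/noisy pass pair and their differences."""

    ell: np.ndarray                       # (T,) clean per-step losses
    ell_noisy: Optional[np.ndarray] = None
    delta_ell: Optional[np.ndarray] = field(default=None)

    def __post_init__(self) -> None:
        if self.ell_noisy is not None and self.delta_ell is None:
            self.delta_ell = self.ell_noisy - self.ell

    @property
    def L(self) -> float:
        """Sequence loss: mean of the per-timestep clean losses."""
        return float(np.mean(self.ell))

    @property
    def L_noisy(self) -> float:
        return float(np.mean(self.ell_noisy))

    @property
    def delta_L(self) -> float:
        """Global loss difference used by the per-sequence rule variants."""
        return self.L_noisy - self.L


def init_params(
    input_dim: int,
    hidden_dim: int,
    output_dim: int,
    decorrelate: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> RNNParams:
    """Initialize weights uniformly in [-1/sqrt(fan_in), 1/sqrt(fan_in)].

    The decorrelation matrix, when enabled, starts at the identity so the
    decorrelated network is initially equivalent to the plain one.
    """
    rng = np.random.default_rng(rng)

    def uniform(rows: int, cols: int) -> np.ndarray:
        bound = 1.0 / np.sqrt(cols)
        return rng.uniform(-bound, bound, size=(rows, cols))

    return RNNParams(
        A=uniform(hidden_dim, input_dim),
        R=uniform(hidden_dim, hidden_dim),
        B=uniform(output_dim, hidden_dim),
        D=np.eye(hidden_dim) if decorrelate else None,
    )


def _check_inputs(params: RNNParams, u: np.ndarray, x0: Optional[np.ndarray]):
    u = np.atleast_2d(np.asarray(u, dtype=float))
    if u.shape[1] != params.input_dim:
        raise ShapeError(
            f"input sequence has {u.shape[1]} channels, A expects {params.input_dim}"
        )
    if x0 is None:
        x0 = np.zeros(params.hidden_dim)
    else:
        x0 = np.asarray(x0, dtype=float)
        if x0.shape != (params.hidden_dim,):
            raise ShapeError(f"x0 has shape {x0.shape}, expected ({params.hidden_dim},)")
        if not np.all(np.isfinite(x0)):
            raise ShapeError("x0 contains non-finite entries")
    return u, x0


def forward_clean(
    params: RNNParams, u: np.ndarray, x0: Optional[np.ndarray] = None
) -> Trajectory:
    """Run the deterministic forward pass over a full input sequence.

    When ``params.D`` is present the decorrelated dynamics are used: the
    recurrence consumes x*_{t-1} = D x_{t-1} and the readout maps x*_t.
    """
    u, x0 = _check_inputs(params, u, x0)
    T = u.shape[0]
    H, O = params.hidden_dim, params.output_dim
    decorrelated = params.D is not None

    alpha = np.empty((T, H))
    x = np.empty((T, H))
    x_star = np.empty((T, H)) if decorrelated else None
    prev = params.D @ x0 if decorrelated else x0
    pre0 = prev.copy()
    for t in range(T):
        alpha[t] = params.A @ u[t] + params.R @ prev
        x[t] = np.tanh(alpha[t])
        if decorrelated:
            x_star[t] = params.D @ x[t]
            prev = x_star[t]
        else:
            prev = x[t]
    readout = x_star if decorrelated else x
    beta = readout @ params.B.T
    return Trajectory(u=u, alpha=alpha, x=x, beta=beta, y=beta.copy(),
                      x_star=x_star, pre0=pre0)


def forward_clean_decorrelated(
    params: RNNParams, u: np.ndarray, x0: Optional[np.ndarray] = None
) -> Trajectory:
    """Clean forward pass through the decorrelated architecture (D required)."""
    if params.D is None:
        raise ConfigurationError("decorrelated forward pass requires params.D")
    return forward_clean(params, u, x0)


def forward_noisy_node(
    params: RNNParams,
    u: np.ndarray,
    x0: Optional[np.ndarray] = None,
    sigma: float = 1e-3,
    rng: Optional[np.random.Generator] = None,
) -> NoisyTrajectory:
    """Forward pass with fresh Gaussian noise on every pre-activation.

    Hidden noise xi_t enters before the nonlinearity, output noise nu_t is
    added to the readout.  The noisy recurrence propagates its own state.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    u, x0 = _check_inputs(params, u, x0)
    rng = np.random.default_rng(rng)
    T = u.shape[0]
    H, O = params.hidden_dim, params.output_dim
    decorrelated = params.D is not None

    xi = rng.normal(0.0, sigma, size=(T, H))
    nu = rng.normal(0.0, sigma, size=(T, O))
    alpha = np.empty((T, H))
    x = np.empty((T, H))
    x_star = np.empty((T, H)) if decorrelated else None
    beta = np.empty((T, O))
    prev = params.D @ x0 if decorrelated else x0
    pre0 = prev.copy()
    for t in range(T):
        alpha[t] = params.A @ u[t] + params.R @ prev + xi[t]
        x[t] = np.tanh(alpha[t])
        state = params.D @ x[t] if decorrelated else x[t]
        if decorrelated:
            x_star[t] = state
        beta[t] = params.B @ state + nu[t]
        prev = state
    return NoisyTrajectory(
        u=u, alpha=alpha, x=x, beta=beta, y=beta.copy(), x_star=x_star,
        pre0=pre0, node_noise={"xi": xi, "nu": nu},
    )


def forward_noisy_weight(
    params: RNNParams,
    u: np.ndarray,
    x0: Optional[np.ndarray] = None,
    sigma: float = 1e-3,
    rng: Optional[np.random.Generator] = None,
) -> NoisyTrajectory:
    """Forward pass with fresh Gaussian noise added to every weight matrix.

    At each step the effective weights are A + xi_t, R + nu_t, B + zeta_t,
    with independent draws per timestep.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    u, x0 = _check_inputs(params, u, x0)
    rng = np.random.default_rng(rng)
    T = u.shape[0]
    H = params.hidden_dim
    decorrelated = params.D is not None

    xi = rng.normal(0.0, sigma, size=(T,) + params.A.shape)
    nu = rng.normal(0.0, sigma, size=(T,) + params.R.shape)
    zeta = rng.normal(0.0, sigma, size=(T,) + params.B.shape)
    alpha = np.empty((T, H))
    x = np.empty((T, H))
    x_star = np.empty((T, H)) if decorrelated else None
    beta = np.empty((T, params.output_dim))
    prev = params.D @ x0 if decorrelated else x0
    pre0 = prev.copy()
    for t in range(T):
        alpha[t] = (params.A + xi[t]) @ u[t] + (params.R + nu[t]) @ prev
        x[t] = np.tanh(alpha[t])
        state = params.D @ x[t] if decorrelated else x[t]
        if decorrelated:
            x_star[t] = state
        beta[t] = (params.B + zeta[t]) @ state
        prev = state
    return NoisyTrajectory(
        u=u, alpha=alpha, x=x, beta=beta, y=beta.copy(), x_star=x_star,
        pre0=pre0, weight_noise={"xi": xi, "nu": nu, "zeta": zeta},
    )


def sequence_loss(y: np.ndarray, y_star: np.ndarray) -> LossRecord:
    """Per-timestep squared-error losses ell_t = ||y_t - y*_t||^2 and their mean."""
    y = np.atleast_2d(np.asarray(y, dtype=float))
    y_star = np.atleast_2d(np.asarray(y_star, dtype=float))
    if y.shape != y_star.shape:
        raise ShapeError(f"outputs {y.shape} and targets {y_star.shape} differ")
    ell = np.sum((y - y_star) ** 2, axis=1)
    return LossRecord(ell=ell)


def loss_record(
    clean: Trajectory, noisy: NoisyTrajectory, y_star: np.ndarray
) -> LossRecord:
    """Loss record for a clean/noisy pass pair against shared targets."""
    y_star = np.atleast_2d(np.asarray(y_star, dtype=float))
    ell = sequence_loss(clean.y, y_star).ell
    ell_noisy = sequence_loss(noisy.y, y_star).ell
    return LossRecord(ell=ell, ell_noisy=ell_noisy)


def save_params(params: RNNParams, path) -> None:
    """Serialize parameters to a .npz archive with a JSON metadata entry."""
    meta = {
        "input_dim": params.input_dim,
        "hidden_dim": params.hidden_dim,
        "output_dim": params.output_dim,
        "activation": "tanh",
        "decorrelated": params.D is not None,
    }
    arrays = {"A": params.A, "R": params.R, "B": params.B,
              "meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
    if params.D is not None:
        arrays["D"] = params.D
    np.savez(path, **arrays)


def load_params(path) -> RNNParams:
    with np.load(path) as data:
        return RNNParams(
            A=data["A"], R=data["R"], B=data["B"],
            D=data["D"] if "D" in data else None,
        )
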