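"""Seeded synthetic benchmark generators and dataset plumbing.

Three sequence-prediction benchmarks:

* Mackey-Glass — a one-dimensional chaotic series from the delay
  differential equation dx/dt = beta*x(t-tau)/(1+x(t-tau)^n) - gamma*x(t),
  integrated with unit-step Euler; the network predicts the series
  ``horizon`` steps ahead.  With the canonical constants (beta=0.2,
  gamma=0.1, n=10) and tau=17 the series is chaotic; small tau relaxes to a
  fixed point.
* Copying memory — the network observes a one-hot symbol sequence, waits
  through a marked delay period, and must reproduce the sequence exactly
  when cued.
* Synthetic weather — a multivariate surrogate for hourly climate records:
  every channel shares a slow daily (period-24) component plus per-channel
  autoregressive noise, and the target is the temperature-like channel
  shifted ``horizon`` steps into the future.

Every generator is a pure function of its parameter tuple including the
seed: regeneration with identical meta reproduces identical data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

__all__ = [
    "SequenceDataset",
    "gen_mackey_glass",
    "mackey_glass_series",
    "gen_copy_memory",
    "gen_synthetic_weather",
    "train_test_split",
    "standardize",
    "weather_from_csv",
]


@dataclass
class SequenceDataset:
    """A list of (input sequence, target sequence) pairs plus provenance."""

    inputs: List[np.ndarray]   # each (T, input_dim)
    targets: List[np.ndarray]  # each (T, output_dim)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.inputs) != len(self.targets):
            raise ValueError("inputs and targets must have equal length")
        for i, (u, y) in enumerate(zip(self.inputs, self.targets)):
            if u.shape[0] != y.shape[0]:
                raise ValueError(f"sequence {i}: input T={u.shape[0]} != target T={y.shape[0]}")

    def __len__(self) -> int:
        return len(self.inputs)

    @property
    def input_dim(self) -> int:
        return self.inputs[0].shape[1]

    @property
    def output_dim(self) -> int:
        return self.targets[0].shape[1]

    def save(self, path) -> None:
        """Serialize to a .npz archive; meta goes in as a JSON entry."""
        arrays = {}
        for i, (u, y) in enumerate(zip(self.inputs, self.targets)):
            arrays[f"input_{i}"] = u
            arrays[f"target_{i}"] = y
        arrays["meta"] = np.frombuffer(
            json.dumps(self.meta).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    def to_csv(self, path) -> None:
        """Flat CSV export: one row per timestep, columns = channels."""
        import pandas as pd

        frames = []
        for i, (u, y) in enumerate(zip(self.inputs, self.targets)):
            df = pd.DataFrame(u, columns=[f"in_{j}" for j in range(u.shape[1])])
            for j in range(y.shape[1]):
                df[f"target_{j}"] = y[:, j]
            df.insert(0, "t", np.arange(u.shape[0]))
            df.insert(0, "sequence", i)
            frames.append(df)
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)

    @staticmethod
    def load(path) -> "SequenceDataset":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode()) if "meta" in data else {}
            n = sum(1 for k in data.files if k.startswith("input_"))
            return SequenceDataset(
                inputs=[data[f"input_{i}"] for i in range(n)],
                targets=[data[f"target_{i}"] for i in range(n)],
                meta=meta,
            )


def mackey_glass_series(
    n_total: int,
    tau: int = 17,
    beta: float = 0.2,
    gamma: float = 0.1,
    n: int = 10,
    x0: float = 1.2,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Integrate the Mackey-Glass delay differential equation (unit-step Euler).

    History is constant at ``x0``; a small seed-dependent jitter on the
    initial value separates realizations for multi-seed experiments (the
    dynamics themselves are deterministic).
    """
    if n_total < 1 or tau < 1:
        raise ValueError("n_total and tau must be positive")
    if seed is not None:
        x0 = x0 + np.random.default_rng(seed).uniform(-0.05, 0.05)
    x = np.empty(n_total + tau)
    x[:tau] = x0
    for t in range(tau, n_total + tau):
        x[t] = x[t - 1] + beta * x[t - tau] / (1.0 + x[t - tau] ** n) - gamma * x[t - 1]
    return x[tau:]


def gen_mackey_glass(
    n_steps: int = 5000,
    tau: int = 17,
    horizon: int = 15,
    seed: int = 0,
    burn_in: int = 100,
    n_sequences: int = 1,
) -> SequenceDataset:
    """Mackey-Glass prediction task: input x(t), target x(t + horizon).

    ``n_sequences`` consecutive windows of length ``n_steps`` are cut from
    one long integration (after discarding ``burn_in`` samples), so windows
    are chronologically ordered — suitable for a chronological split.
    """
    if n_steps < 1 or horizon < 1 or n_sequences < 1:
        raise ValueError("n_steps, horizon and n_sequences must be positive")
    total = burn_in + n_sequences * n_steps + horizon
    series = mackey_glass_series(total, tau=tau, seed=seed)
    series = series[burn_in:]
    inputs, targets = [], []
    for i in range(n_sequences):
        lo = i * n_steps
        inputs.append(series[lo:lo + n_steps, None].copy())
        targets.append(series[lo + horizon:lo + n_steps + horizon, None].copy())
    meta = {
        "task": "mackey_glass", "n_steps": n_steps, "tau": tau,
        "horizon": horizon, "seed": seed, "burn_in": burn_in,
        "n_sequences": n_sequences,
    }
    return SequenceDataset(inputs=inputs, targets=targets, meta=meta)


def gen_copy_memory(
    seq_len: int = 100,
    delay: int = 10,
    n_symbols: int = 8,
    seed: int = 0,
    n_sequences: int = 1,
) -> SequenceDataset:
    """Copying-memory task with one-hot symbols and marker channels.

    Input has ``n_symbols + 2`` channels: the one-hot symbol channels, a
    delay-marker channel active throughout the delay period, and a recall
    cue active one step before the recall window.  The timeline is
    ``seq_len + delay + 1 + seq_len`` steps; targets are zero (the blank
    convention) everywhere except the recall window, which holds the
    original symbol sequence one-hot.
    """
    if n_symbols < 2:
        raise ValueError("n_symbols must be at least 2")
    if seq_len < 1 or delay < 0 or n_sequences < 1:
        raise ValueError("invalid dimensions")
    rng = np.random.default_rng(seed)
    T = seq_len + delay + 1 + seq_len
    inputs, targets = [], []
    for _ in range(n_sequences):
        symbols = rng.integers(0, n_symbols, size=seq_len)
        u = np.zeros((T, n_symbols + 2))
        y = np.zeros((T, n_symbols))
        u[np.arange(seq_len), symbols] = 1.0
        u[seq_len:seq_len + delay, n_symbols] = 1.0      # delay marker
        u[seq_len + delay, n_symbols + 1] = 1.0          # recall cue
        recall = seq_len + delay + 1
        y[recall + np.arange(seq_len), symbols] = 1.0
        inputs.append(u)
        targets.append(y)
    meta = {
        "task": "copy_memory", "seq_len": seq_len, "delay": delay,
        "n_symbols": n_symbols, "seed": seed, "n_sequences": n_sequences,
    }
    return SequenceDataset(inputs=inputs, targets=targets, meta=meta)


def gen_synthetic_weather(
    n_steps: int = 720,
    n_features: int = 6,
    horizon: int = 24,
    seed: int = 0,
    n_sequences: int = 1,
    period: int = 24,
    ar_coeff: float = 0.8,
    ar_scale: float = 0.3,
    daily_amplitude: float = 2.0,
) -> SequenceDataset:
    """Synthetic hourly-weather surrogate: predict the temperature channel
    ``horizon`` steps ahead.

    All channels share a slow periodic component (period 24 on the step
    grid, i.e. a daily cycle) scaled by a per-channel random coupling, plus
    independent AR(1) noise.  Channel 0 plays the temperature role and is
    the prediction target.  Windows are chronological, so a chronological
    train/test split mimics training on early months and testing on the
    last ones.
    """
    if n_steps < 1 or n_features < 1 or horizon < 1 or n_sequences < 1:
        raise ValueError("n_steps, n_features, horizon, n_sequences must be positive")
    rng = np.random.default_rng(seed)
    total = n_sequences * n_steps + horizon
    t = np.arange(total)
    daily = np.sin(2 * np.pi * t / period)
    coupling = rng.uniform(0.5, 1.5, size=n_features)
    phase = rng.uniform(0, 2 * np.pi, size=n_features)
    phase[0] = 0.0  # the target channel carries the reference daily cycle
    channels = np.empty((total, n_features))
    for j in range(n_features):
        ar = np.empty(total)
        ar[0] = rng.normal(0, ar_scale)
        eps = rng.normal(0, ar_scale, size=total)
        for i in range(1, total):
            ar[i] = ar_coeff * ar[i - 1] + eps[i]
        channels[:, j] = (
            daily_amplitude * coupling[j] * np.sin(2 * np.pi * t / period + phase[j]) + ar
        )
    inputs, targets = [], []
    for i in range(n_sequences):
        lo = i * n_steps
        inputs.append(channels[lo:lo + n_steps].copy())
        targets.append(channels[lo + horizon:lo + n_steps + horizon, 0:1].copy())
    meta = {
        "task": "synthetic_weather", "n_steps": n_steps,
        "n_features": n_features, "horizon": horizon, "seed": seed,
        "n_sequences": n_sequences, "period": period, "ar_coeff": ar_coeff,
        "ar_scale": ar_scale, "daily_amplitude": daily_amplitude,
    }
    return SequenceDataset(inputs=inputs, targets=targets, meta=meta)


def weather_from_csv(
    path,
    target_column: str = "DryBulb",
    horizon: int = 24,
    feature_columns: Optional[List[str]] = None,
    n_steps: int = 720,
) -> SequenceDataset:
    """Build a prediction dataset from a user-supplied hourly weather CSV.

    Expects one row per hour with named feature columns; the target column
    (air temperature by default) is predicted ``horizon`` hours ahead.
    Rows are windowed into consecutive ``n_steps``-long sequences, so a
    chronological split afterwards trains on early months and tests on the
    last ones.
    """
    import pandas as pd

    df = pd.read_csv(path)
    if target_column not in df.columns:
        raise ValueError(f"target column {target_column!r} not in {list(df.columns)}")
    feats = feature_columns or [c for c in df.columns if df[c].dtype.kind in "fi"]
    if target_column not in feats:
        feats = [target_column] + feats
    X = df[feats].to_numpy(dtype=float)
    y = df[target_column].to_numpy(dtype=float)
    usable = (len(df) - horizon) // n_steps
    if usable < 1:
        raise ValueError("file too short for one window at this horizon")
    inputs, targets = [], []
    for i in range(usable):
        lo = i * n_steps
        inputs.append(X[lo:lo + n_steps].copy())
        targets.append(y[lo + horizon:lo + n_steps + horizon, None].copy())
    meta = {"task": "weather_csv", "source": str(path), "horizon": horizon,
            "n_steps": n_steps, "features": feats, "target": target_column}
    return SequenceDataset(inputs=inputs, targets=targets, meta=meta)


def train_test_split(
    ds: SequenceDataset, fraction: float = 0.8, chronological: bool = True,
    seed: Optional[int] = None,
) -> Tuple[SequenceDataset, SequenceDataset]:
    """Split sequences into disjoint, exhaustive train/test partitions.

    ``fraction`` is the train share.  Chronological keeps generation order
    (test sequences strictly follow train sequences); otherwise a seeded
    shuffle decides membership.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    n = len(ds)
    n_train = int(round(fraction * n))
    if n_train == 0 or n_train == n:
        raise ValueError(f"degenerate split: {n_train} train of {n} sequences")
    idx = np.arange(n)
    if not chronological:
        np.random.default_rng(seed).shuffle(idx)
    tr, te = idx[:n_train], idx[n_train:]

    def subset(sel, role):
        meta = dict(ds.meta, split=role, indices=[int(i) for i in sel])
        return SequenceDataset(
            inputs=[ds.inputs[i] for i in sel],
            targets=[ds.targets[i] for i in sel],
            meta=meta,
        )

    return subset(tr, "train"), subset(te, "test")


def standardize(
    train: SequenceDataset, test: Optional[SequenceDataset] = None,
    targets_too: bool = True,
) -> Tuple[SequenceDataset, Optional[SequenceDataset]]:
    """Z-score inputs (and optionally targets) using train statistics only."""
    xs = np.concatenate(train.inputs, axis=0)
    mu, sd = xs.mean(axis=0), xs.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    if targets_too:
        ys = np.concatenate(train.targets, axis=0)
        tmu, tsd = ys.mean(axis=0), ys.std(axis=0)
        tsd = np.where(tsd > 0, tsd, 1.0)

    def apply(ds: SequenceDataset, role: str) -> SequenceDataset:
        return SequenceDataset(
            inputs=[(u - mu) / sd for u in ds.inputs],
            targets=[(y - tmu) / tsd for y in ds.targets] if targets_too
            else [y.copy() for y in ds.targets],
            meta=dict(ds.meta, standardized=True),
        )

    return apply(train, "train"), None if test is None else apply(test, "test")
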