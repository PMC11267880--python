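"""Experiment configuration schema and builders.

A single YAML file describes an experiment in five blocks — task, model,
rule, training, output — validated strictly (unknown keys are rejected with
their field paths) before anything runs.  All randomness flows from the
seeds declared here: data generation uses the task seed, each training run
derives its independent streams from its own run seed.
"""

from __future__ import annotations

from typing import List, Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .rules import RuleConfig
from .tasks import (
    SequenceDataset,
    gen_copy_memory,
    gen_mackey_glass,
    gen_synthetic_weather,
    standardize,
    train_test_split,
)
from .train import RunConfig

__all__ = ["ExperimentConfig", "load_config", "build_datasets", "build_run_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TaskBlock(_Strict):
    name: Literal["mackey_glass", "copy_memory", "synthetic_weather"]
    seed: int = 0
    n_sequences: int = Field(2, ge=2)
    split_fraction: float = Field(0.5, gt=0, lt=1)
    chronological: bool = True
    standardize: bool = True
    # generator-specific knobs (validated per task below)
    n_steps: Optional[int] = None
    tau: Optional[int] = None
    horizon: Optional[int] = None
    burn_in: Optional[int] = None
    seq_len: Optional[int] = None
    delay: Optional[int] = None
    n_symbols: Optional[int] = None
    n_features: Optional[int] = None


class ModelBlock(_Strict):
    hidden_dim: int = Field(64, ge=1)
    decorrelate: bool = False


class RuleBlock(_Strict):
    rule_name: Literal["np_local", "np_global", "anp", "wp_local", "wp_global", "bp"] = "anp"
    sigma: float = 1e-3
    anp_uses_delta_loss: bool = True
    presynaptic_convention: Literal["corrected", "as_printed"] = "corrected"
    anp_normalization: Literal["joint", "per_layer"] = "joint"
    N: Optional[int] = None


class TrainingBlock(_Strict):
    eta: float = Field(1e-4, ge=0)
    epsilon: float = Field(1e-5, ge=0)
    epochs: int = Field(100, ge=1)
    seeds: List[int] = Field(default=[1, 2, 3, 4, 5], min_length=1)
    loss_threshold: float = 1e6
    weight_bound: float = 1e6
    update_cadence: Literal["sequence", "online"] = "sequence"
    final_window: int = Field(50, ge=1)


class OutputBlock(_Strict):
    directory: str = "results"
    formats: List[Literal["csv", "json"]] = ["csv", "json"]


class ExperimentConfig(_Strict):
    task: TaskBlock
    model: ModelBlock = ModelBlock()
    rule: RuleBlock = RuleBlock()
    training: TrainingBlock = TrainingBlock()
    output: OutputBlock = OutputBlock()


def load_config(path) -> ExperimentConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    return ExperimentConfig.model_validate(raw)


def _drop_none(**kwargs) -> dict:
    return {k: v for k, v in kwargs.items() if v is not None}


def generate_dataset(cfg: ExperimentConfig) -> SequenceDataset:
    """Run the task block's generator with its declared parameters."""
    t = cfg.task
    if t.name == "mackey_glass":
        return gen_mackey_glass(
            seed=t.seed, n_sequences=t.n_sequences,
            **_drop_none(n_steps=t.n_steps, tau=t.tau, horizon=t.horizon,
                         burn_in=t.burn_in),
        )
    if t.name == "copy_memory":
        return gen_copy_memory(
            seed=t.seed, n_sequences=t.n_sequences,
            **_drop_none(seq_len=t.seq_len, delay=t.delay, n_symbols=t.n_symbols),
        )
    return gen_synthetic_weather(
        seed=t.seed, n_sequences=t.n_sequences,
        **_drop_none(n_steps=t.n_steps, n_features=t.n_features, horizon=t.horizon),
    )


def build_datasets(cfg: ExperimentConfig):
    """Generate, split, and (for the continuous tasks) standardize."""
    ds = generate_dataset(cfg)
    train, test = train_test_split(
        ds, fraction=cfg.task.split_fraction, chronological=cfg.task.chronological,
        seed=cfg.task.seed,
    )
    if cfg.task.standardize and cfg.task.name != "copy_memory":
        train, test = standardize(train, test)
    return train, test


def build_run_config(cfg: ExperimentConfig) -> RunConfig:
    train, test = build_datasets(cfg)
    rule = RuleConfig(
        rule_name=cfg.rule.rule_name, sigma=cfg.rule.sigma,
        anp_uses_delta_loss=cfg.rule.anp_uses_delta_loss,
        presynaptic_convention=cfg.rule.presynaptic_convention,
        anp_normalization=cfg.rule.anp_normalization, N=cfg.rule.N,
    )
    return RunConfig(
        train_data=train, test_data=test, hidden_dim=cfg.model.hidden_dim,
        rule=rule, eta=cfg.training.eta, epsilon=cfg.training.epsilon,
        epochs=cfg.training.epochs, seeds=list(cfg.training.seeds),
        decorrelate=cfg.model.decorrelate,
        loss_threshold=cfg.training.loss_threshold,
        weight_bound=cfg.training.weight_bound,
        update_cadence=cfg.training.update_cadence,
    )
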