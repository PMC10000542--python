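"""Run configuration: YAML-backed settings for every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .simulate import CohortConfig

__all__ = [
    "ConfigError",
    "PartitionSettings",
    "LearnerSettings",
    "ProgressionSettings",
    "RunConfig",
]


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class PartitionSettings:
    lower: float = 0.4
    upper: float = 0.6
    core_features: tuple[str, ...] = ("Jitter(%)", "Shimmer")

    def validate(self) -> None:
        if not 0 <= self.lower < self.upper:
            raise ConfigError(
                f"DA thresholds must satisfy 0 <= lower < upper, got {self.lower}, {self.upper}"
            )


@dataclass
class LearnerSettings:
    hidden_size: int = 8
    epochs: int = 300
    learning_rate: float = 0.5
    momentum: float = 0.9
    sq_decay: float = 0.9
    damping: float = 1e-6
    gamma_init: float = 0.25
    loss: str = "mse"
    threshold: float = 0.5
    #: features the learner consults: the core measures plus the additional
    #: NHR/RPDE/DFA observations raised by the augmentation rule
    features: tuple[str, ...] = ("Jitter(%)", "Shimmer", "NHR", "RPDE", "DFA")

    def validate(self) -> None:
        if self.hidden_size <= 0 or self.epochs < 0:
            raise ConfigError("hidden_size must be positive and epochs nonnegative")
        if self.loss not in ("mse", "xent"):
            raise ConfigError(f"unknown loss {self.loss!r}")


@dataclass
class ProgressionSettings:
    threshold: float = 0.06
    feature: str = "Jitter:RAP"
    mode: str = "da"
    aggregate: str = "max"

    def validate(self) -> None:
        if self.threshold < 0:
            raise ConfigError("progression threshold must be nonnegative")
        if self.mode not in ("da", "model"):
            raise ConfigError(f"unknown progression mode {self.mode!r}")


@dataclass
class RunConfig:
    """Everything a pipeline run needs, reproducible from config + seed alone."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    partition: PartitionSettings = field(default_factory=PartitionSettings)
    learner: LearnerSettings = field(default_factory=LearnerSettings)
    progression: ProgressionSettings = field(default_factory=ProgressionSettings)
    retrain_fraction: float = 0.2
    dialect: str = "uci22"
    #: fraction of subjects held out for record-level evaluation
    test_fraction: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        self.cohort.validate()
        self.partition.validate()
        self.learner.validate()
        self.progression.validate()
        if not 0 <= self.retrain_fraction <= 1:
            raise ConfigError("retrain_fraction must lie in [0, 1]")
        if not 0 < self.test_fraction < 1:
            raise ConfigError("test_fraction must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            payload = yaml.safe_load(Path(path).read_text()) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config {path}: {exc}") from exc
        return cls.from_dict(payload)

    @classmethod
    def from_dict(cls, payload: Mapping) -> "RunConfig":
        payload = dict(payload)
        try:
            cohort = CohortConfig.from_dict(payload.pop("cohort", {}))
            partition = _settings(PartitionSettings, payload.pop("partition", {}))
            learner = _settings(LearnerSettings, payload.pop("learner", {}))
            progression = _settings(ProgressionSettings, payload.pop("progression", {}))
            cfg = cls(
                cohort=cohort,
                partition=partition,
                learner=learner,
                progression=progression,
                **payload,
            )
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc
        cfg.validate()
        return cfg


def _settings(cls, payload: Mapping):
    payload = dict(payload)
    for key in ("core_features", "features"):
        if isinstance(payload.get(key), list):
            payload[key] = tuple(payload[key])
    try:
        return cls(**payload)
    except TypeError as exc:
        raise ConfigError(f"bad {cls.__name__} settings: {exc}") from exc
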