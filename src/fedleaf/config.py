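"""Experiment configuration types.

``ExperimentConfig`` gathers the federated hyper-parameters — number of
clients C, communication rounds R, local epochs E_c, batch size B_c and
local learning rate L_R — together with the dataset, model, split and seed
choices that make a run reproducible.  ``SweepSpec`` names one axis to vary
while everything else is held at the base configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Union

import yaml

from .model_core import ModelSpec
from .synthetic_data import SyntheticDatasetSpec

SWEEP_AXES = ("n_clients", "rounds", "local_epochs", "dataset")


@dataclass(frozen=True)
class ExperimentConfig:
    """All knobs of one federated run.

    Defaults follow the experimental grid commonly used for this task
    (batch size 16, learning rate 0.01, 3 clients) at desk scale: a
    synthetic 4-class dataset and the native tiny_cnn.
    """

    dataset: Union[str, SyntheticDatasetSpec] = field(
        default_factory=SyntheticDatasetSpec
    )
    model: ModelSpec = field(default_factory=ModelSpec)
    n_clients: int = 3
    rounds: int = 10
    local_epochs: int = 1
    batch_size: int = 16
    learning_rate: float = 0.01
    test_fraction: float = 0.2
    base_seed: int = 0
    averaging: str = "macro"
    stats_source: str = "computed"

    def validate(self) -> None:
        for name in ("n_clients", "rounds", "local_epochs", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.learning_rate <= 0:
            raise ValueError(
                f"learning_rate must be > 0, got {self.learning_rate}"
            )
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError(
                f"test_fraction must lie in (0, 1), got {self.test_fraction}"
            )
        if self.averaging not in ("macro", "micro"):
            raise ValueError(f"averaging must be macro|micro, got {self.averaging!r}")
        if self.stats_source not in ("computed", "preset"):
            raise ValueError(
                f"stats_source must be computed|preset, got {self.stats_source!r}"
            )
        self.model.validate()
        if isinstance(self.dataset, SyntheticDatasetSpec):
            self.dataset.validate()

    def with_value(self, axis: str, value) -> "ExperimentConfig":
        if axis not in SWEEP_AXES:
            raise ValueError(f"axis must be one of {SWEEP_AXES}, got {axis!r}")
        return replace(self, **{axis: value})

    def to_dict(self) -> dict:
        d = asdict(self)
        d["model"]["input_size"] = list(self.model.input_size)
        if isinstance(self.dataset, SyntheticDatasetSpec):
            d["dataset"]["image_size"] = list(self.dataset.image_size)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if isinstance(d.get("model"), dict):
            m = dict(d["model"])
            if "input_size" in m:
                m["input_size"] = tuple(m["input_size"])
            d["model"] = ModelSpec(**m)
        if isinstance(d.get("dataset"), dict):
            ds = dict(d["dataset"])
            if "image_size" in ds:
                ds["image_size"] = tuple(ds["image_size"])
            d["dataset"] = SyntheticDatasetSpec(**ds)
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class SweepSpec:
    """One config axis to vary; all other parameters held at ``base``."""

    base: ExperimentConfig
    axis: str
    values: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(self.values))

    def validate(self) -> None:
        self.base.validate()
        if self.axis not in SWEEP_AXES:
            raise ValueError(
                f"axis must be one of {SWEEP_AXES}, got {self.axis!r}"
            )
        if not self.values:
            raise ValueError("sweep values must be non-empty")

    @classmethod
    def from_yaml(cls, path) -> "SweepSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        base = ExperimentConfig.from_dict(d["base"])
        return cls(base=base, axis=d["axis"], values=tuple(d["values"]))
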