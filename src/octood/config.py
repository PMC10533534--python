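"""Run configuration: a schema-validated YAML front end composing the
dataset, training, exposure and benchmark settings.

Unknown keys are rejected up front (``extra="forbid"``), so a typo in a
config file fails before any computation starts, naming the offending
key.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .augment import AugmentConfig
from .synthgen import NEAR_OOD_CLASSES, DatasetConfig
from .train import ExposureConfig, TrainConfig

__all__ = ["RunConfig", "load_run_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DatasetSection(_Strict):
    images_per_class: int = 200
    images_per_subject: int = 1
    side: int = 64
    layer_contrast: float = 0.40
    drusen_amplitude: float = 1.0
    fluid_blob_scale: float = 1.0
    atrophy_depth: float = 0.55
    noise_sigma: float = 0.03
    split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    exposure_pool_fraction: float = 0.5

    def build(self, seed: int) -> DatasetConfig:
        cfg = DatasetConfig(seed=seed, **self.model_dump())
        cfg.validate()
        return cfg


class TrainSection(_Strict):
    preset: str = "desk_scale"  # or "reference" for the original schedule
    batch_size: int | None = None
    learning_rate: float | None = None
    momentum: float | None = None
    max_epochs: int | None = None
    early_stop_patience: int | None = None
    lr_patience: int | None = None
    oe_lambda: float | None = None
    augment: bool = True

    @field_validator("preset")
    @classmethod
    def _preset_known(cls, v):
        if v not in ("desk_scale", "reference"):
            raise ValueError("preset must be 'desk_scale' or 'reference'")
        return v

    def build(self, seed: int) -> TrainConfig:
        cfg = (TrainConfig.desk_scale(seed=seed) if self.preset == "desk_scale"
               else TrainConfig(seed=seed))
        for name in ("batch_size", "learning_rate", "momentum", "max_epochs",
                     "early_stop_patience", "lr_patience", "oe_lambda"):
            v = getattr(self, name)
            if v is not None:
                setattr(cfg, name, v)
        if not self.augment:
            cfg.augment = AugmentConfig.disabled()
        return cfg


class ExposureSection(_Strict):
    classes: tuple[str, ...] = NEAR_OOD_CLASSES
    n_per_class: int = 0
    batch_prob: float = 0.5
    replicate: int = 0

    def build(self) -> ExposureConfig:
        cfg = ExposureConfig(**self.model_dump())
        cfg.validate()
        return cfg


class BenchmarkSection(_Strict):
    methods: tuple[str, ...] | None = None
    metrics: tuple[str, ...] | None = None
    exposure_n: int = 4
    n_repeats: int = 20
    ensemble_size: int = 20
    n_boot: int = 100
    shrinkage: float = 0.1


class SweepSection(_Strict):
    methods: tuple[str, ...] = ("softmax_oe_ent", "softmax_oe_rb")
    class_sets: tuple[tuple[str, ...], ...] = (
        ("DME",), ("RVO",), ("Stargardt",), NEAR_OOD_CLASSES)
    n_values: tuple[int, ...] = (1, 2, 4, 8, 16)
    replicates: int = 5
    n_boot: int = 100


class RunConfig(_Strict):
    """Top-level run description; every field has a sane default, so an
    empty file is a valid (if heavy) full run."""

    seed: int = 0
    outdir: str = "results"
    verbosity: int = 1
    dataset: DatasetSection = Field(default_factory=DatasetSection)
    train: TrainSection = Field(default_factory=TrainSection)
    exposure: ExposureSection = Field(default_factory=ExposureSection)
    benchmark: BenchmarkSection = Field(default_factory=BenchmarkSection)
    sweep: SweepSection = Field(default_factory=SweepSection)


def load_run_config(path: str | Path) -> RunConfig:
    """Parse and schema-validate a YAML run config. Raises a ValueError
    naming the offending key on schema violations."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return RunConfig.model_validate(raw)
    except Exception as exc:  # re-raise with a plain message for the CLI
        raise ValueError(f"invalid run config {path}: {exc}") from exc
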