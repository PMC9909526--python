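"""Pipeline configuration: a YAML-backed, schema-validated model.

``PipelineConfig`` mirrors the stage parameter sets field-for-field
(simulator, spectrogram, the two detector specs, training) plus the
global seed and working paths.  Unknown keys are rejected; every
violation is reported, not just the first.  Configurations round-trip
losslessly through YAML.
"""

from __future__ import annotations

import hashlib
import json
import os

from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator


class SimulatorSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_scenes: int = 20
    scene_duration_s: float = 5.0
    sample_rate: float = 96000.0
    events_per_scene: tuple[int, int] = (0, 3)
    snr_range_db: tuple[float, float] = (5.0, 25.0)
    spectral_slope: float = -5.0
    transient_rate: float = 1.0
    ship_tonals: list[tuple[float, float]] = []
    level_db: float = -30.0


class SpectrogramSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    window_len: int = 2048
    window_type: str = "blackman"
    hop: int | None = None
    segment_len_s: float = 0.8
    segment_shift_s: float = 0.4
    f_min: float = 3000.0
    f_max: float = 20000.0
    db_floor: float = -120.0

    @model_validator(mode="after")
    def _check(self):
        hop = self.hop if self.hop is not None else int(round(0.8 * self.window_len))
        if not (0 < hop <= self.window_len):
            raise ValueError(f"hop ({hop}) must be in (0, window_len]")
        if not self.f_min < self.f_max:
            raise ValueError("f_min must be below f_max")
        if self.segment_shift_s > self.segment_len_s:
            raise ValueError("segment_shift_s must not exceed segment_len_s")
        return self


class PreprocessSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    band_low_hz: float = 5000.0
    band_high_hz: float = 20000.0
    denoise: bool = False
    detect_cutoffs: bool = False

    @model_validator(mode="after")
    def _check(self):
        if not 0 < self.band_low_hz < self.band_high_hz:
            raise ValueError("need 0 < band_low_hz < band_high_hz")
        return self


class VanillaSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    conv_blocks: list[tuple[int, int, int]] = [(16, 7, 2), (32, 5, 2)]
    pool_size: int = 2
    dropout_rate: float = 0.2
    dense_sizes: list[int] = [32, 16]
    learning_rate: float = 1e-4


class TransferSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    backbone: str = "vgg16"
    head_dense_sizes: list[int] = [50, 20]
    fine_tune_all: bool = True
    learning_rate: float = 1e-5


class TrainingSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    model: Literal["vanilla", "transfer"] = "vanilla"
    max_epochs: int = Field(200, ge=1)
    batch_size: int = Field(32, ge=1)
    early_stopping_patience: int = Field(15, ge=1)
    validation_fraction: float = Field(0.2, ge=0.0, lt=1.0)
    cv_folds: int = Field(5, ge=0)


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    work_dir: str = "whistlekit-run"
    simulator: SimulatorSection = SimulatorSection()
    preprocess: PreprocessSection = PreprocessSection()
    spectrogram: SpectrogramSection = SpectrogramSection()
    vanilla: VanillaSection = VanillaSection()
    transfer: TransferSection = TransferSection()
    training: TrainingSection = TrainingSection()

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(os.fspath(path), "w") as fh:
            yaml.safe_dump(json.loads(self.model_dump_json()), fh, sort_keys=False)

    def content_hash(self) -> str:
        return hashlib.sha256(self.model_dump_json().encode()).hexdigest()[:16]


def validate_config(path: str | os.PathLike) -> PipelineConfig:
    """Load and validate a YAML config; raise with every violation listed."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return PipelineConfig.model_validate(raw)
    except ValidationError as exc:
        msgs = [
            f"{'.'.join(str(l) for l in e['loc'])}: {e['msg']}" for e in exc.errors()
        ]
        raise ValueError("invalid configuration:\n  " + "\n  ".join(msgs)) from exc
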