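"""YAML run configuration with schema validation and provenance records."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import OsteofuzzError
from .calibrate import DESettings
from .params import ModelParameters

__all__ = ["RunConfig", "load_config", "ConfigError", "provenance_record"]


class ConfigError(OsteofuzzError):
    """Configuration file failed validation; message names the field."""


class DEConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    pop: int = Field(default=45, ge=4)
    generations: int = Field(default=200, ge=1)
    f: float = Field(default=0.8, gt=0.0, lt=2.0)
    cr: float = Field(default=0.9, gt=0.0, le=1.0)


class CalibrationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_runs: int = Field(default=20, ge=2)
    base_seed: int = Field(default=0, ge=0)
    tolerance: float = Field(default=0.05, gt=0.0)
    free_parameters: list[str] | None = None


class SensitivityConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    lssp_magnitude: float = Field(default=0.5, gt=0.0, lt=1.0)
    ssip_magnitude: float = Field(default=0.15, gt=0.0, lt=1.0)
    resolution: int = Field(default=4, ge=3, le=4)


class RunConfig(BaseModel):
    """Validated run configuration.

    ``parameters`` overrides entries of the default 30-parameter registry;
    unknown names are rejected.
    """

    model_config = ConfigDict(extra="forbid")
    parameters: dict[str, float] = Field(default_factory=dict)
    dt: float = Field(default=1.0, gt=0.0)
    studies: list[int] = Field(default=[1, 2, 3, 4, 5])
    noise_cv: float = Field(default=0.1, ge=0.0)
    de: DEConfig = Field(default_factory=DEConfig)
    calibration: CalibrationConfig = Field(default_factory=CalibrationConfig)
    sensitivity: SensitivityConfig = Field(default_factory=SensitivityConfig)

    def model_parameters(self) -> ModelParameters:
        try:
            return ModelParameters().replace(**self.parameters)
        except TypeError as exc:
            raise ConfigError(f"unknown parameter in config: {exc}") from exc

    def de_settings(self) -> DESettings:
        return DESettings(
            pop=self.de.pop,
            generations=self.de.generations,
            f=self.de.f,
            cr=self.de.cr,
        )


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML config; ``None`` yields the defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"]) or "<root>"
        raise ConfigError(f"invalid config field {loc!r}: {first['msg']}") from exc


def provenance_record(config: RunConfig, seeds: list[int], extra: dict | None = None) -> dict:
    """Reproducibility record: config hash, seeds and package version."""
    from . import __version__

    payload = json.dumps(config.model_dump(), sort_keys=True).encode()
    record = {
        "config_sha256": hashlib.sha256(payload).hexdigest(),
        "seeds": seeds,
        "package_version": __version__,
    }
    if extra:
        record.update(extra)
    return record
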