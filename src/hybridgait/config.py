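"""Run configuration: schema-validated YAML/JSON round trip.

A :class:`RunConfig` gathers everything a closed-loop experiment needs —
linkage geometry, controller gains, filter settings, subject calibration,
plant parameters and the run conditions (mode, speed, cycles, seed).
Unknown keys are rejected and validation errors name the offending key, so
a typo in a config file fails loudly instead of silently using a default.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .coordination import K_MAX_DEFAULT, K_MIN_DEFAULT, ZETA_DEFAULT, SubjectCalibration
from .filters import FilterConfig
from .linkage import LinkageGeometry, PDGains
from .simulate import PlantParams

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config"]


class ConfigError(ValueError):
    """Configuration schema violation; the message names the key."""


@dataclass
class RunConfig:
    """Validated configuration of one simulation experiment."""

    mode: str = "PFV"
    speed_kmh: float = 1.8
    n_cycles: int = 4
    seed: int = 0
    alpha: float = 0.5
    dt: float = 1e-3
    k_min: float = K_MIN_DEFAULT
    k_max: float = K_MAX_DEFAULT
    zeta: float = ZETA_DEFAULT
    damping_mode: str = "critical"
    model_path: str | None = None  # trained torque-model checkpoint
    out_path: str | None = None
    geometry: LinkageGeometry = field(default_factory=LinkageGeometry)
    gains: PDGains = field(default_factory=PDGains)
    filter: FilterConfig = field(default_factory=FilterConfig)
    calibration: SubjectCalibration = field(default_factory=SubjectCalibration)
    plant: PlantParams = field(default_factory=PlantParams)

    def __post_init__(self) -> None:
        if self.mode not in ("PF", "PFV"):
            raise ConfigError(f"mode: must be 'PF' or 'PFV', got {self.mode!r}")
        if not 1.0 <= self.speed_kmh <= 5.0:
            raise ConfigError(f"speed_kmh: {self.speed_kmh} outside [1, 5]")
        if self.n_cycles < 2:
            raise ConfigError(f"n_cycles: need >= 2, got {self.n_cycles}")
        if not self.k_min < self.k_max:
            raise ConfigError(
                f"k_min/k_max: require k_min < k_max, got {self.k_min} >= {self.k_max}"
            )
        if self.zeta < 0:
            raise ConfigError(f"zeta: must be nonnegative, got {self.zeta}")
        if self.damping_mode not in ("literal", "critical"):
            raise ConfigError(f"damping_mode: {self.damping_mode!r} unknown")
        if self.model_path is not None and not Path(self.model_path).exists():
            raise ConfigError(f"model_path: {self.model_path} does not exist")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


_NESTED = {
    "geometry": LinkageGeometry,
    "gains": PDGains,
    "filter": FilterConfig,
    "calibration": SubjectCalibration,
    "plant": PlantParams,
}


def _build_nested(cls, data: dict, key: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"{key}: unknown keys {sorted(unknown)}")
    # YAML reads tuples back as lists
    for f in dataclasses.fields(cls):
        if f.name in data and isinstance(data[f.name], list):
            data[f.name] = tuple(data[f.name])
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{key}: {exc}") from exc


def load_config(path: "str | Path") -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file {path} not found")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    top_allowed = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - top_allowed
    if unknown:
        raise ConfigError(f"unknown keys {sorted(unknown)}")
    kwargs = {}
    for key, value in raw.items():
        if key in _NESTED:
            if not isinstance(value, dict):
                raise ConfigError(f"{key}: must be a mapping")
            kwargs[key] = _build_nested(_NESTED[key], dict(value), key)
        else:
            kwargs[key] = value
    try:
        return RunConfig(**kwargs)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def save_config(config: RunConfig, path: "str | Path") -> None:
    """Write a config as YAML (JSON-compatible types only)."""
    path = Path(path)
    d = config.to_dict()
    path.write_text(yaml.safe_dump(json.loads(json.dumps(d)), sort_keys=False))
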