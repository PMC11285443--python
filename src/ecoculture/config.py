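"""Run configuration: schema, file loading (TOML/YAML) and round-tripping.

A config file has up to five sections -- ``model``, ``forcing``,
``ensemble``, ``sync`` and ``output`` -- each mapping onto the corresponding
dataclass.  Unknown keys are rejected with their full key path.  A config
emitted into run metadata loads back to an identical configuration.
"""

from __future__ import annotations

import dataclasses
import math
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

from .errors import ConfigError, ParameterError
from .forcing import ClimateForcing
from .model import ModelParameters

__all__ = [
    "EnsembleConfig",
    "SyncConfig",
    "OutputConfig",
    "RunConfig",
    "load_config",
    "config_from_dict",
]


@dataclass(frozen=True)
class EnsembleConfig:
    n_members: int = 16
    seed_base: int = 0
    burn_in: int = 0

    def __post_init__(self):
        if self.n_members < 1:
            raise ConfigError("ensemble.n_members must be >= 1")
        if self.burn_in < 0:
            raise ConfigError("ensemble.burn_in must be >= 0")


@dataclass(frozen=True)
class SyncConfig:
    n_bins: int = 36
    edge_fraction: float = 0.05
    detrend: bool = False
    log_culture: bool = False
    decimate_ks: bool = False
    decimation_stride: Optional[int] = None

    def __post_init__(self):
        if self.n_bins < 2:
            raise ConfigError("sync.n_bins must be >= 2")
        if not 0 <= self.edge_fraction < 0.5:
            raise ConfigError("sync.edge_fraction must lie in [0, 0.5)")


@dataclass(frozen=True)
class OutputConfig:
    directory: str = "."
    compress: bool = False


@dataclass(frozen=True)
class RunConfig:
    model: ModelParameters = field(default_factory=ModelParameters)
    forcing: Optional[ClimateForcing] = None
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    sync: SyncConfig = field(default_factory=SyncConfig)
    output: OutputConfig = field(default_factory=OutputConfig)

    def resolved_forcing(self) -> ClimateForcing:
        """Explicit forcing section, else the one implied by model fields."""
        if self.forcing is not None:
            return self.forcing
        return self.model.default_forcing()

    def to_dict(self) -> dict:
        """JSON-serializable dict that round-trips via config_from_dict."""
        out: dict[str, Any] = {"model": dataclasses.asdict(self.model)}
        if self.forcing is not None:
            out["forcing"] = dataclasses.asdict(self.forcing)
        out["ensemble"] = dataclasses.asdict(self.ensemble)
        out["sync"] = dataclasses.asdict(self.sync)
        out["output"] = dataclasses.asdict(self.output)
        return out


_SECTIONS = {
    "model": ModelParameters,
    "forcing": ClimateForcing,
    "ensemble": EnsembleConfig,
    "sync": SyncConfig,
    "output": OutputConfig,
}


def _build_section(name: str, cls, data: dict):
    if not isinstance(data, dict):
        raise ConfigError(f"section {name!r} must be a table/mapping")
    known = {f.name for f in dataclasses.fields(cls)}
    extra_handlers = {"period"} if name == "forcing" else set()
    unknown = set(data) - known - extra_handlers
    if unknown:
        key = sorted(unknown)[0]
        raise ConfigError(f"unknown key {name}.{key}")
    data = dict(data)
    if name == "forcing" and "period" in data:
        if "omega" in data:
            raise ConfigError(
                "forcing.period and forcing.omega are mutually exclusive"
            )
        period = data.pop("period")
        if not (isinstance(period, (int, float)) and period > 0):
            raise ConfigError("forcing.period must be a positive number")
        data["omega"] = 2.0 * math.pi / period
    try:
        return cls(**data)
    except ParameterError as exc:
        # prefix the offending parameter with its section path
        raise ConfigError(f"{name}: {exc}") from exc
    except TypeError as exc:
        raise ConfigError(f"{name}: {exc}") from exc


def config_from_dict(data: dict) -> RunConfig:
    """Validate a nested mapping into a RunConfig (defaults filled)."""
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    unknown = set(data) - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"unknown section {sorted(unknown)[0]!r}")
    kwargs: dict[str, Any] = {}
    for name, cls in _SECTIONS.items():
        if name in data:
            kwargs[name] = _build_section(name, cls, data[name])
    return RunConfig(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a TOML (default) or YAML configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    else:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    return config_from_dict(data)
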