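"""Run configuration: built-in defaults, optional YAML file, CLI overrides."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import yaml

from .exceptions import ConfigurationError
from .mechanics import NYLON66_DENSITY

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Defaults shared by all CLI commands.

    Precedence: CLI flags > config file > these built-ins.  Unknown keys in
    a config file are rejected rather than silently ignored.
    """

    density: float = NYLON66_DENSITY  # kg m^-3
    boundary: str = "clamped_pinned"
    k_factor: Optional[float] = None  # only for boundary == "custom"
    nominal_force: float = 10.0  # gf
    tolerance_band: float = 10.0  # +/- %
    rounding: bool = False  # apply instrument display rounding to outputs
    output_dir: str = "."
    seed: int = 0

    def __post_init__(self) -> None:
        for key in ("density", "nominal_force", "tolerance_band"):
            if not (getattr(self, key) > 0):
                raise ConfigurationError(f"config key {key} must be positive")
        if self.seed < 0:
            raise ConfigurationError("config key seed must be >= 0")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        """Load a flat key-value YAML file, rejecting unknown keys."""
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config file {path} must be a flat mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(
                f"unknown config keys in {path}: {sorted(unknown)}"
            )
        return cls(**raw)

    def with_overrides(self, **overrides) -> "RunConfig":
        """New config with non-None overrides applied (CLI flags win)."""
        values = {k: v for k, v in overrides.items() if v is not None}
        return dataclasses.replace(self, **values)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
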