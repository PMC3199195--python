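"""Study configuration: serialisable settings for the whole pipeline.

A :class:`StudyConfig` captures everything needed to re-run a study cell
bit-identically: model parameters, integrator settings, synchronisation
criterion settings, scan grids and output paths.  Configs round-trip
through YAML, and a short content hash is embedded in every output file
for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .model import CouplingParams, RepressilatorParams
from .simulate import IntegratorSettings

__all__ = ["StudyConfig", "ConfigError"]

#: the study's relevant coupling range; values outside are allowed but flagged
STUDY_DIFF_RANGE = (0.01, 0.13)


class ConfigError(ValueError):
    pass


@dataclass
class StudyConfig:
    params: RepressilatorParams = field(default_factory=RepressilatorParams)
    integrator: IntegratorSettings = field(default_factory=IntegratorSettings)
    epsilon_fraction: float = 1.0 / 1440.0
    hold_cycles: int = 10
    horizon_periods: float = 200.0
    phase_grid: list[float] = field(
        default_factory=lambda: [i * 10.0 for i in range(36)]
    )
    ratio_grid: list[float] = field(
        default_factory=lambda: [0.65 + 0.7 * i / 24 for i in range(25)]
    )
    diff_grid: list[float] = field(
        default_factory=lambda: [0.01, 0.03, 0.05, 0.07, 0.09, 0.11, 0.13]
    )
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if self.epsilon_fraction <= 0:
            raise ConfigError("epsilon_fraction: must be positive")
        if self.hold_cycles < 1:
            raise ConfigError("hold_cycles: must be >= 1")
        if self.horizon_periods <= 0:
            raise ConfigError("horizon_periods: must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def hash(self) -> str:
        """Short deterministic content hash for output provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def out_of_study_range(self) -> list[float]:
        lo, hi = STUDY_DIFF_RANGE
        return [d for d in self.diff_grid if not lo <= d <= hi]

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        try:
            if "params" in d:
                d["params"] = RepressilatorParams(**d["params"])
            if "integrator" in d:
                d["integrator"] = IntegratorSettings(**d["integrator"])
            return cls(**d)
        except TypeError as err:
            raise ConfigError(str(err)) from err

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
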