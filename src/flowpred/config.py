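"""Run configuration: serializable bundle of every tunable of the pipeline.

Defaults reproduce the study conditions (40 participants, 13 repetitions
per prediction condition, 30-37-trial staircases, the default population
parameters).  Configs round-trip through YAML and every artifact written
by the CLI embeds the config hash and master seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields

import yaml

from .calibration import CalibrationConfig
from .observer import PopulationParams

__all__ = ["RunConfig", "load_config", "save_config", "config_hash"]


@dataclass(frozen=True)
class AnalysisConfig:
    alpha: float = 0.05
    n_boot: int = 1000
    method: str = "bootstrap"  # reporting route; the power loop always uses wald


@dataclass(frozen=True)
class DesignConfig:
    n_participants: int = 40
    repetitions: int = 13
    pest_min_trials: int = 30
    pest_max_trials: int = 37
    head_bins: int = 0


@dataclass(frozen=True)
class RunConfig:
    population: PopulationParams = field(default_factory=PopulationParams)
    design: DesignConfig = field(default_factory=DesignConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["calibration"]["bounds"] = list(d["calibration"]["bounds"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def build(klass, sub: dict):
            allowed = {f.name for f in fields(klass)}
            unknown = set(sub) - allowed
            if unknown:
                raise ValueError(f"unknown {klass.__name__} keys: {sorted(unknown)}")
            return klass(**sub)

        calib = dict(d.get("calibration", {}))
        if "bounds" in calib:
            calib["bounds"] = tuple(calib["bounds"])
        return cls(
            population=build(PopulationParams, d.get("population", {})),
            design=build(DesignConfig, d.get("design", {})),
            analysis=build(AnalysisConfig, d.get("analysis", {})),
            calibration=build(CalibrationConfig, calib),
            seed=int(d.get("seed", 0)),
        )


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


def config_hash(cfg: RunConfig) -> str:
    """Short stable hash identifying a configuration."""
    text = yaml.safe_dump(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:12]
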