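"""Run configuration: one object, YAML-serializable, carrying every
numeric constant the pipeline uses so a run is reproducible from the
config plus its seed."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import preprocess
from .model import R_SQUARED_EXCLUSION
from .simulate import DEFAULT_GROUPS, DEFAULT_SEED, GroupParams, RTModel


@dataclass
class Thresholds:
    min_rt_ms: float = preprocess.MIN_RT_MS
    sd_multiplier: float = preprocess.SD_MULTIPLIER
    error_rate_threshold: float = preprocess.ERROR_RATE_THRESHOLD
    r2_exclusion: float = R_SQUARED_EXCLUSION
    counting_window_ms: float = preprocess.COUNTING_WINDOW_MS

    def __post_init__(self) -> None:
        for name in dataclasses.asdict(self):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")


@dataclass
class StatsOptions:
    alpha: float = 0.05
    levene_center: str = "mean"
    #: outcome column in the participant summary -> covariate columns
    outcomes: dict[str, list[str]] = field(
        default_factory=lambda: {
            "w_number": ["rpm"],
            "w_time": ["rpm"],
            "number_hits": ["rpm"],
            "symbolic_rt": ["ran"],
            "subitizing_rt": ["rpm", "ran"],
            "enumeration_rt": ["rpm", "ran"],
        }
    )


@dataclass
class RunConfig:
    seed: int = DEFAULT_SEED
    groups: tuple[GroupParams, ...] = DEFAULT_GROUPS
    thresholds: Thresholds = field(default_factory=Thresholds)
    stats: StatsOptions = field(default_factory=StatsOptions)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "groups": [dataclasses.asdict(g) for g in self.groups],
            "thresholds": dataclasses.asdict(self.thresholds),
            "stats": dataclasses.asdict(self.stats),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        groups = tuple(
            GroupParams(
                **{
                    **g,
                    "rt_model": RTModel(**g["rt_model"]),
                    "w_number": tuple(g["w_number"]),
                    "w_time": tuple(g["w_time"]),
                    "covariate_rpm": tuple(g["covariate_rpm"]),
                    "covariate_ran": tuple(g["covariate_ran"]),
                }
            )
            for g in d.get("groups", [])
        ) or DEFAULT_GROUPS
        return cls(
            seed=int(d.get("seed", DEFAULT_SEED)),
            groups=groups,
            thresholds=Thresholds(**d.get("thresholds", {})),
            stats=StatsOptions(**d.get("stats", {})),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def digest(self) -> str:
        """Short stable hash of the full configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
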