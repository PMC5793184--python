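"""Pipeline configuration: every stage threshold in one serialisable object.

Defaults are the published operating points of the workflow: 50-bp windows
merged to <= 2 kb with FDR < 0.05 and fold change > 1.25 for discovery;
2-kb upstream promoters; PWM relative score > 0.85; miRNA target score
> 50; time-course min SD 0.5, membership 0.6, six clusters; validation with
>= 5 differential CpGs at FDR 0.05 and fold change > 1.25; enrichment at
Holm-adjusted p < 0.05.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .dmr import DmrConfig
from .methio import ReadQCParams
from .simulate import SimulationConfig


@dataclass(frozen=True)
class TimecourseConfig:
    min_sd: float = 0.5
    membership_min: float = 0.6
    c: int = 6
    m: float = 1.25
    seed: int = 0


@dataclass(frozen=True)
class ValidationConfig:
    min_cpgs: int = 5
    fdr: float = 0.05
    fc: float = 1.25


@dataclass(frozen=True)
class PathsConfig:
    input_dir: str | None = None  # None = generate synthetic inputs
    output_dir: str = "dmrlink_run"


@dataclass(frozen=True)
class PipelineConfig:
    dmr: DmrConfig = field(default_factory=DmrConfig)
    qc: ReadQCParams = field(default_factory=ReadQCParams)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    timecourse: TimecourseConfig = field(default_factory=TimecourseConfig)
    validation: ValidationConfig = field(default_factory=ValidationConfig)
    paths: PathsConfig = field(default_factory=PathsConfig)
    promoter_upstream: int = 2000
    pwm_threshold: float = 0.85
    mirna_score_min: float = 50.0
    enrichment_alpha: float = 0.05
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        nested = {
            "dmr": DmrConfig, "qc": ReadQCParams, "simulation": SimulationConfig,
            "timecourse": TimecourseConfig, "validation": ValidationConfig,
            "paths": PathsConfig,
        }
        kwargs = {}
        for key, value in data.items():
            if key in nested:
                sub_cls = nested[key]
                allowed = {f.name for f in dataclasses.fields(sub_cls)}
                unknown = set(value) - allowed
                if unknown:
                    raise ValueError(f"unknown keys in '{key}': {sorted(unknown)}")
                if sub_cls is SimulationConfig:
                    for tup in ("dmr_length_range", "baseline_beta_params"):
                        if tup in value and isinstance(value[tup], list):
                            value[tup] = tuple(value[tup])
                kwargs[key] = sub_cls(**value)
            elif key in {f.name for f in dataclasses.fields(cls)}:
                kwargs[key] = value
            else:
                raise ValueError(f"unknown configuration key: {key}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()
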