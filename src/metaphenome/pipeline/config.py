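"""Pipeline configuration: stage toggles, paths and stage parameters.

Configs validate strictly (unknown keys are rejected) and a serialized
copy is stored with every run so results are reproducible from the run
directory alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from ..synthcohort.config import SimulationConfig

STAGES = ("simulate", "preprocess", "scan", "preonset", "ageing", "metrs")


class PipelineConfigError(ValueError):
    pass


@dataclass
class StageToggles:
    simulate: bool = True
    preprocess: bool = True
    scan: bool = True
    preonset: bool = True
    ageing: bool = True
    metrs: bool = True


@dataclass
class ScanParams:
    alpha: float = 0.05
    min_cases: int = 300
    trait_min_n: int = 10_000
    binary_min_cell: int = 50
    include_egfr: bool = False  # eGFR-adjusted sensitivity covariate set
    subgroups: bool = False
    kinds: list | None = None  # subset of {prevalent, incident, traits}; None = all


@dataclass
class PreonsetParams:
    bins: int = 15
    ratio: int = 5
    alpha: float = 0.05
    min_cases_per_bin: int = 10
    convention: str = "stopping_bin"
    min_cases: int = 50  # diseases below this skip pre-onset profiling


@dataclass
class AgeingParams:
    span: float = 0.75
    width: int = 3
    k_min: int = 2
    k_max: int = 12
    min_parcel: int = 30


@dataclass
class MetrsParams:
    k_folds: int = 10
    top_k: int = 30
    n_bootstrap: int = 1000
    min_cases: int = 100
    max_iter: int = 100


@dataclass
class PipelineConfig:
    out_dir: str = "run"
    cohort_dir: str | None = None  # None -> the simulate stage must be enabled
    seed: int = 0
    stages: StageToggles = field(default_factory=StageToggles)
    simulate: SimulationConfig = field(default_factory=SimulationConfig)
    scan: ScanParams = field(default_factory=ScanParams)
    preonset: PreonsetParams = field(default_factory=PreonsetParams)
    ageing: AgeingParams = field(default_factory=AgeingParams)
    metrs: MetrsParams = field(default_factory=MetrsParams)

    def validate(self) -> None:
        if not self.stages.simulate and self.cohort_dir is None:
            raise PipelineConfigError("cohort_dir required when the simulate stage is disabled")
        self.simulate.validate()
        if self.preonset.convention not in ("stopping_bin", "last_significant"):
            raise PipelineConfigError("unknown preonset convention")
        if self.ageing.width not in (2, 3, 4, 5):
            raise PipelineConfigError("ageing width must be one of 2,3,4,5")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulate"] = self.simulate.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise PipelineConfigError(f"unknown config keys: {sorted(unknown)}")
        for key, sub_cls in (
            ("stages", StageToggles),
            ("scan", ScanParams),
            ("preonset", PreonsetParams),
            ("ageing", AgeingParams),
            ("metrs", MetrsParams),
        ):
            if key in d and isinstance(d[key], dict):
                extra = set(d[key]) - set(sub_cls.__dataclass_fields__)
                if extra:
                    raise PipelineConfigError(f"unknown keys under {key!r}: {sorted(extra)}")
                d[key] = sub_cls(**d[key])
        if "simulate" in d and isinstance(d["simulate"], dict):
            d["simulate"] = SimulationConfig.from_dict(d["simulate"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        cfg = cls.from_dict(yaml.safe_load(Path(path).read_text()))
        cfg.validate()
        return cfg

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)
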