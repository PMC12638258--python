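"""Configuration types for the synthetic cohort generator.

Every planted parameter lives in these dataclasses so that a simulated
bundle carries its own ground truth.  Configs round-trip losslessly through
``to_dict``/``from_dict`` (and therefore through YAML/JSON).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import yaml


class ConfigurationError(ValueError):
    """Raised when a simulation config violates its invariants."""


RAMP_SHAPES = ("linear", "step")
DISEASE_MODES = ("hazard_driven", "divergence_driven", "null")
TRAIT_KINDS = ("continuous", "ordinal", "binary")


@dataclass
class DivergenceSpec:
    """Pre-onset divergence planted on one metabolite of future cases."""

    metabolite: int
    emergence_time: float  # years before onset at which divergence begins
    shift: float  # shift reached at onset, in latent SD units
    ramp: str = "linear"

    def validate(self, horizon: float) -> None:
        if self.ramp not in RAMP_SHAPES:
            raise ConfigurationError(f"unknown ramp shape {self.ramp!r}")
        if not 0 < self.emergence_time <= horizon:
            raise ConfigurationError(
                f"emergence_time must lie in (0, {horizon}], got {self.emergence_time}"
            )


@dataclass
class DiseaseSpec:
    disease_id: str
    mode: str = "null"
    prevalence_prevalent: float = 0.05
    incidence_scale: float = 0.002  # baseline hazard, events per year
    effect_metabolites: list = field(default_factory=list)  # [(index, log-HR/log-OR per SD)]
    divergence: Optional[DivergenceSpec] = None

    def validate(self, n_metabolites: int, horizon: float) -> None:
        if self.mode not in DISEASE_MODES:
            raise ConfigurationError(f"unknown disease mode {self.mode!r}")
        if not 0 < self.prevalence_prevalent < 1:
            raise ConfigurationError("prevalence_prevalent must be in (0,1)")
        if self.incidence_scale <= 0:
            raise ConfigurationError("incidence_scale must be positive")
        for idx, _ in self.effect_metabolites:
            if not 0 <= int(idx) < n_metabolites:
                raise ConfigurationError(f"effect metabolite index {idx} out of range")
        if (self.mode == "divergence_driven") != (self.divergence is not None):
            raise ConfigurationError(
                "divergence spec is required iff mode == 'divergence_driven'"
            )
        if self.divergence is not None:
            self.divergence.validate(horizon)
            if not 0 <= self.divergence.metabolite < n_metabolites:
                raise ConfigurationError("divergence metabolite index out of range")


@dataclass
class TraitSpec:
    trait_id: str
    kind: str = "continuous"
    effect_metabolites: list = field(default_factory=list)  # [(index, coefficient per SD)]
    n_ordinal_levels: int = 4
    noise_sd: float = 1.0
    binary_prevalence: float = 0.5

    def validate(self, n_metabolites: int) -> None:
        if self.kind not in TRAIT_KINDS:
            raise ConfigurationError(f"unknown trait kind {self.kind!r}")
        if self.kind == "ordinal" and self.n_ordinal_levels < 3:
            raise ConfigurationError("ordinal traits need >= 3 levels")
        if self.kind == "binary" and not 0 < self.binary_prevalence < 1:
            raise ConfigurationError("binary_prevalence must be in (0,1)")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        for idx, _ in self.effect_metabolites:
            if not 0 <= int(idx) < n_metabolites:
                raise ConfigurationError(f"effect metabolite index {idx} out of range")


@dataclass
class WaveSpec:
    """A sigmoidal age-wave planted on one metabolite's mean level."""

    metabolite: int
    crest_age: float
    amplitude: float  # SD units reached across the transition
    width: float = 4.0  # years over which most of the transition happens


@dataclass
class CovariateConfig:
    """Stylized covariate distributions.

    The source cohort's joint covariate distribution is not published;
    these defaults are deliberately simple and clearly labelled synthetic.
    """

    age_min: float = 40.0
    age_max: float = 70.0
    p_female: float = 0.54
    ethnicity_levels: list = field(default_factory=lambda: ["white", "asian", "black", "other"])
    ethnicity_probs: list = field(default_factory=lambda: [0.95, 0.02, 0.02, 0.01])
    tdi_mean: float = 0.0
    tdi_sd: float = 3.0
    bmi_mean: float = 27.0
    bmi_sd: float = 4.5
    smoking_levels: list = field(default_factory=lambda: ["never", "former", "current"])
    smoking_probs: list = field(default_factory=lambda: [0.55, 0.35, 0.10])
    p_statin: float = 0.15
    fasting_mean_hours: float = 4.0
    n_centres: int = 22
    include_egfr: bool = False
    egfr_mean: float = 90.0
    egfr_sd: float = 13.0
    missing_rate: float = 0.02
    missing_columns: list = field(default_factory=lambda: ["tdi", "bmi", "smoking", "fasting_time"])


@dataclass
class SimulationConfig:
    n_participants: int = 2000
    n_metabolites: int = 313
    metabolite_block_structure: list = field(default_factory=list)  # [(block size, rho)]
    covariates: CovariateConfig = field(default_factory=CovariateConfig)
    disease_specs: list = field(default_factory=list)
    trait_specs: list = field(default_factory=list)
    ageing_wave_specs: list = field(default_factory=list)
    age_trend_slope: float = 0.0  # SD of latent level per year, applied to all metabolites
    follow_up_horizon: float = 15.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1 or self.n_metabolites < 1:
            raise ConfigurationError("n_participants and n_metabolites must be >= 1")
        if self.follow_up_horizon <= 0:
            raise ConfigurationError("follow_up_horizon must be positive")
        total = 0
        for size, rho in self.metabolite_block_structure:
            if not -1.0 <= rho <= 1.0:
                raise ConfigurationError(f"block correlation {rho} outside [-1, 1]")
            if size < 1:
                raise ConfigurationError("block sizes must be >= 1")
            # equicorrelation matrix is PSD iff rho >= -1/(size-1)
            if size > 1 and rho < -1.0 / (size - 1):
                raise ConfigurationError(
                    f"block of size {size} with correlation {rho} is not positive semi-definite"
                )
            total += size
        if total > self.n_metabolites:
            raise ConfigurationError("block sizes sum exceeds n_metabolites")
        seen = set()
        for spec in self.disease_specs:
            if spec.disease_id in seen:
                raise ConfigurationError(f"duplicate disease_id {spec.disease_id!r}")
            seen.add(spec.disease_id)
            spec.validate(self.n_metabolites, self.follow_up_horizon)
        seen = set()
        for spec in self.trait_specs:
            if spec.trait_id in seen:
                raise ConfigurationError(f"duplicate trait_id {spec.trait_id!r}")
            seen.add(spec.trait_id)
            spec.validate(self.n_metabolites)
        for wave in self.ageing_wave_specs:
            if not 0 <= wave.metabolite < self.n_metabolites:
                raise ConfigurationError("wave metabolite index out of range")
            if wave.width <= 0:
                raise ConfigurationError("wave width must be positive")

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        return _listify(d)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["covariates"] = CovariateConfig(**d.get("covariates", {}))
        d["disease_specs"] = [
            DiseaseSpec(
                **{
                    **s,
                    "divergence": DivergenceSpec(**s["divergence"])
                    if s.get("divergence")
                    else None,
                    "effect_metabolites": [list(e) for e in s.get("effect_metabolites", [])],
                }
            )
            for s in d.get("disease_specs", [])
        ]
        d["trait_specs"] = [
            TraitSpec(**{**s, "effect_metabolites": [list(e) for e in s.get("effect_metabolites", [])]})
            for s in d.get("trait_specs", [])
        ]
        d["ageing_wave_specs"] = [WaveSpec(**w) for w in d.get("ageing_wave_specs", [])]
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(text))


def _listify(obj):
    """Convert tuples (and numpy scalars) to plain python for YAML round-trips."""
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_listify(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
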