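"""Synthetic cohort generation with planted, recorded ground truth.

The metabolite panel is generated on a latent Gaussian scale (block
equicorrelation structure) and exponentiated to a positive, right-skewed
raw scale, so the downstream log/z QC chain is exercised non-trivially.
Disease registries and traits are generated from the latent z-scale with
known effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .config import ConfigurationError, DiseaseSpec, SimulationConfig, TraitSpec

__all__ = ["CohortBundle", "simulate_cohort", "simulate_registry", "simulate_traits"]

_COVARIATE_COLUMNS = [
    "age",
    "sex",
    "ethnicity",
    "tdi",
    "bmi",
    "smoking",
    "statin",
    "fasting_time",
    "assessment_centre",
]


@dataclass
class CohortBundle:
    """One simulated (or ingested) cohort: covariates, metabolites, outcomes."""

    participants: pd.DataFrame
    metabolites: pd.DataFrame  # raw (positive) scale, index = participant id
    registry: pd.DataFrame
    traits: pd.DataFrame
    ground_truth: Optional[dict] = field(default=None)

    @property
    def participant_ids(self) -> pd.Index:
        return self.participants.index


def _substream(seed: int, label: str) -> np.random.Generator:
    """Independent named substream so stage toggling does not shift draws."""
    tag = int.from_bytes(label.encode(), "little") % (2**31)
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


def _wave_term(age: np.ndarray, crest: float, amplitude: float, width: float) -> np.ndarray:
    # sigmoid transition centred at the crest age; the scale width/4 puts
    # ~96% of the amplitude inside [crest - width, crest + width]
    return amplitude * expit((age - crest) / (width / 4.0))


def _latent_matrix(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    n, m = config.n_participants, config.n_metabolites
    z = rng.standard_normal((n, m))
    start = 0
    for size, rho in config.metabolite_block_structure:
        if size > 1 and rho != 0.0:
            block = np.full((size, size), rho, dtype=float)
            np.fill_diagonal(block, 1.0)
            try:
                chol = np.linalg.cholesky(block)
            except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by validate
                raise ConfigurationError(
                    f"block correlation matrix not positive definite (size {size}, rho {rho})"
                ) from exc
            z[:, start : start + size] = z[:, start : start + size] @ chol.T
        start += size
    return z


def _covariate_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    cov = config.covariates
    n = config.n_participants
    ids = pd.Index([f"P{i:07d}" for i in range(n)], name="participant_id")
    age = rng.uniform(cov.age_min, cov.age_max, size=n)
    sex = np.where(rng.random(n) < cov.p_female, "female", "male")
    ethnicity = rng.choice(cov.ethnicity_levels, size=n, p=cov.ethnicity_probs)
    tdi = rng.normal(cov.tdi_mean, cov.tdi_sd, size=n)
    bmi = rng.normal(cov.bmi_mean, cov.bmi_sd, size=n)
    smoking = rng.choice(cov.smoking_levels, size=n, p=cov.smoking_probs)
    statin = (rng.random(n) < cov.p_statin).astype(int)
    fasting = rng.gamma(shape=4.0, scale=cov.fasting_mean_hours / 4.0, size=n)
    # unequal multinomial centre sizes (exercises geographic fold balancing)
    weights = np.linspace(1.0, 3.0, cov.n_centres)
    centre_probs = weights / weights.sum()
    centres = rng.choice(
        [f"centre_{i + 1:02d}" for i in range(cov.n_centres)], size=n, p=centre_probs
    )
    table = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "ethnicity": ethnicity,
            "tdi": tdi,
            "bmi": bmi,
            "smoking": smoking,
            "statin": statin,
            "fasting_time": fasting,
            "assessment_centre": centres,
        },
        index=ids,
    )
    if cov.include_egfr:
        table["egfr"] = rng.normal(cov.egfr_mean, cov.egfr_sd, size=n)
    if cov.missing_rate > 0:
        for col in cov.missing_columns:
            mask = rng.random(n) < cov.missing_rate
            if table[col].dtype == object:
                table.loc[mask, col] = None
            else:
                table.loc[mask, col] = np.nan
    return table


def simulate_cohort(config: SimulationConfig) -> CohortBundle:
    """Generate a full cohort bundle; deterministic given ``config.seed``."""
    config.validate()
    participants = _covariate_table(config, _substream(config.seed, "covariates"))
    latent = _latent_matrix(config, _substream(config.seed, "metabolites"))

    age = participants["age"].to_numpy()
    mean_shift = config.age_trend_slope * (age - 55.0)
    latent = latent + mean_shift[:, None]
    for wave in config.ageing_wave_specs:
        latent[:, wave.metabolite] += _wave_term(age, wave.crest_age, wave.amplitude, wave.width)

    raw = np.exp(latent)
    met_cols = [f"met_{j:03d}" for j in range(config.n_metabolites)]
    metabolites = pd.DataFrame(raw, index=participants.index, columns=met_cols)

    bundle = CohortBundle(
        participants=participants,
        metabolites=metabolites,
        registry=pd.DataFrame(
            columns=["participant_id", "disease_id", "status", "onset_time", "censor_time"]
        ),
        traits=pd.DataFrame(index=participants.index),
        ground_truth={"config": config.to_dict()},
    )
    if config.disease_specs:
        bundle.registry = simulate_registry(
            bundle, config.disease_specs, seed=config.seed, horizon=config.follow_up_horizon
        )
    if config.trait_specs:
        bundle.traits = simulate_traits(bundle, config.trait_specs, seed=config.seed)
    return bundle


def _zscale_log(metabolites: pd.DataFrame) -> np.ndarray:
    logged = np.log(metabolites.to_numpy())
    mu = logged.mean(axis=0)
    sd = logged.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (logged - mu) / sd


def simulate_registry(
    bundle: CohortBundle,
    disease_specs: list[DiseaseSpec],
    seed: int,
    horizon: float = 15.0,
) -> pd.DataFrame:
    """Generate prevalent/incident/never outcomes for each disease spec.

    ``divergence_driven`` diseases modify ``bundle.metabolites`` in place:
    cases get ``shift * ramp`` added to the chosen metabolite's log level,
    where the ramp depends on the case's eventual time to onset.
    """
    ids = bundle.participant_ids
    n = len(ids)
    seen: set[str] = set()
    rows = []
    for spec in disease_specs:
        if spec.disease_id in seen:
            raise ConfigurationError(f"disease_id collision: {spec.disease_id!r}")
        seen.add(spec.disease_id)
        rng = _substream(seed, f"registry:{spec.disease_id}")

        lin = np.zeros(n)
        if spec.effect_metabolites:
            z = _zscale_log(bundle.metabolites)
            for idx, beta in spec.effect_metabolites:
                lin += float(beta) * z[:, int(idx)]

        if spec.mode == "null":
            prevalent = rng.random(n) < spec.prevalence_prevalent
            times = rng.exponential(1.0 / spec.incidence_scale, size=n)
        elif spec.mode == "hazard_driven":
            prevalent = rng.random(n) < expit(logit(spec.prevalence_prevalent) + lin)
            hazards = spec.incidence_scale * np.exp(lin)
            times = rng.exponential(1.0, size=n) / hazards
        elif spec.mode == "divergence_driven":
            prevalent = rng.random(n) < spec.prevalence_prevalent
            times = rng.exponential(1.0 / spec.incidence_scale, size=n)
        else:  # pragma: no cover
            raise ConfigurationError(f"unknown mode {spec.mode!r}")

        incident = (~prevalent) & (times <= horizon)
        status = np.where(prevalent, "prevalent", np.where(incident, "incident", "never"))
        onset = np.where(incident, times, np.nan)

        if spec.mode == "divergence_driven":
            div = spec.divergence
            t_onset = onset[incident]
            if div.ramp == "step":
                ramp = (t_onset <= div.emergence_time).astype(float)
            else:
                ramp = np.clip((div.emergence_time - t_onset) / div.emergence_time, 0.0, 1.0)
            col = bundle.metabolites.columns[div.metabolite]
            vals = bundle.metabolites[col].to_numpy(copy=True)
            vals[incident] *= np.exp(div.shift * ramp)
            bundle.metabolites[col] = vals

        rows.append(
            pd.DataFrame(
                {
                    "participant_id": ids,
                    "disease_id": spec.disease_id,
                    "status": status,
                    "onset_time": onset,
                    "censor_time": np.full(n, float(horizon)),
                }
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=["participant_id", "disease_id", "status", "onset_time", "censor_time"]
        )
    return pd.concat(rows, ignore_index=True)


def simulate_traits(
    bundle: CohortBundle, trait_specs: list[TraitSpec], seed: int
) -> pd.DataFrame:
    """Generate continuous / binary / ordinal traits from the z-scaled panel."""
    n = len(bundle.participant_ids)
    z = _zscale_log(bundle.metabolites)
    seen: set[str] = set()
    out = pd.DataFrame(index=bundle.participant_ids)
    for spec in trait_specs:
        if spec.trait_id in seen:
            raise ConfigurationError(f"trait_id collision: {spec.trait_id!r}")
        seen.add(spec.trait_id)
        rng = _substream(seed, f"trait:{spec.trait_id}")
        lin = np.zeros(n)
        for idx, beta in spec.effect_metabolites:
            lin += float(beta) * z[:, int(idx)]
        if spec.kind == "continuous":
            out[spec.trait_id] = lin + rng.normal(0.0, spec.noise_sd, size=n)
        elif spec.kind == "binary":
            p = expit(logit(spec.binary_prevalence) + lin)
            out[spec.trait_id] = (rng.random(n) < p).astype(int)
        else:  # ordinal: threshold a latent Gaussian into equal-mass levels
            latent = lin + rng.normal(0.0, spec.noise_sd, size=n)
            k = spec.n_ordinal_levels
            cuts = np.quantile(latent, np.linspace(0, 1, k + 1)[1:-1])
            out[spec.trait_id] = (np.searchsorted(cuts, latent, side="right") + 1).astype(int)
    return out
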