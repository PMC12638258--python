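import numpy as np
import pandas as pd
import pytest

from metaphenome.preprocess import impute_covariates, qc_transform
from metaphenome.synthcohort import (
    DiseaseSpec,
    DivergenceSpec,
    SimulationConfig,
    TraitSpec,
    WaveSpec,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_participants=4000,
        n_metabolites=10,
        metabolite_block_structure=[[4, 0.7]],
        disease_specs=[
            DiseaseSpec(
                "D_haz", mode="hazard_driven", incidence_scale=0.01,
                effect_metabolites=[[0, 0.6]],
            ),
            DiseaseSpec("D_null", mode="null", incidence_scale=0.008),
            DiseaseSpec(
                "D_div", mode="divergence_driven", incidence_scale=0.015,
                divergence=DivergenceSpec(metabolite=3, emergence_time=6.0, shift=1.2, ramp="step"),
            ),
        ],
        trait_specs=[
            TraitSpec("t_cont", kind="continuous", effect_metabolites=[[1, 0.4]]),
            TraitSpec("t_bin", kind="binary", effect_metabolites=[[2, 0.6]], binary_prevalence=0.3),
            TraitSpec("t_ord", kind="ordinal", n_ordinal_levels=4),
        ],
        ageing_wave_specs=[WaveSpec(metabolite=5, crest_age=55.0, amplitude=1.0)],
        seed=42,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_processed(small_bundle):
    z, _ = qc_transform(small_bundle.metabolites)
    cov, _ = impute_covariates(small_bundle.participants)
    return z, cov


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(7)
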