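"""Association scans: thresholds, analysis sets, model fits, replication."""

import numpy as np
import pandas as pd
import pytest

from metaphenome.assocscan import (
    AssociationRecord,
    bonferroni_threshold,
    build_analysis_sets,
    build_design,
    records_to_frame,
    replicate_fdr,
    scan_associations,
    subgroup_and_interaction,
)
from metaphenome.preprocess import impute_covariates, qc_transform
from metaphenome.synthcohort import DiseaseSpec, SimulationConfig, simulate_cohort


class TestBonferroni:
    def test_published_thresholds(self):
        assert bonferroni_threshold(0.05, 313, 527) == pytest.approx(3.03e-7, rel=5e-3)
        assert bonferroni_threshold(0.05, 313, 859) == pytest.approx(1.86e-7, rel=5e-3)
        assert bonferroni_threshold(0.05, 313, 3142) == pytest.approx(5.08e-8, rel=5e-3)

    def test_identity_case(self):
        assert bonferroni_threshold(0.05, 1, 1) == 0.05

    def test_exact_rational_division(self):
        assert bonferroni_threshold(0.05, 10, 20) == 0.05 / 200

    def test_monotone_decreasing_in_counts(self):
        base = bonferroni_threshold(0.05, 100, 100)
        assert bonferroni_threshold(0.05, 101, 100) < base
        assert bonferroni_threshold(0.05, 100, 101) < base

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0, 10)
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 10, 10)


def _registry(n_prev, n_inc, n_never, disease="D"):
    ids = [f"P{i:05d}" for i in range(n_prev + n_inc + n_never)]
    status = ["prevalent"] * n_prev + ["incident"] * n_inc + ["never"] * n_never
    onset = [np.nan] * n_prev + [5.0] * n_inc + [np.nan] * n_never
    return pd.DataFrame(
        {
            "participant_id": ids,
            "disease_id": disease,
            "status": status,
            "onset_time": onset,
            "censor_time": 15.0,
        }
    )


class TestAnalysisSets:
    def test_299_cases_excluded_with_reason(self):
        sets = build_analysis_sets(_registry(0, 299, 5000))
        inc = next(s for s in sets if s.kind == "incident")
        assert not inc.included
        assert inc.reason == "<300 cases"

    def test_300_cases_included(self):
        sets = build_analysis_sets(_registry(0, 300, 5000))
        inc = next(s for s in sets if s.kind == "incident")
        assert inc.included

    def test_prevalent_absent_from_incident_analysis(self):
        sets = build_analysis_sets(_registry(10, 400, 5000), min_cases=5)
        inc = next(s for s in sets if s.kind == "incident")
        prev_ids = {f"P{i:05d}" for i in range(10)}
        assert prev_ids.isdisjoint(inc.case_ids)
        assert prev_ids.isdisjoint(inc.control_ids)
        assert all(inc.exclusions[i] == "prevalent diagnosis" for i in prev_ids)

    def test_incident_excluded_from_prevalent_analysis(self):
        sets = build_analysis_sets(_registry(400, 10, 5000), min_cases=5)
        prev = next(s for s in sets if s.kind == "prevalent")
        inc_ids = {f"P{i:05d}" for i in range(400, 410)}
        assert inc_ids.isdisjoint(prev.case_ids) and inc_ids.isdisjoint(prev.control_ids)

    def test_cases_controls_disjoint(self):
        sets = build_analysis_sets(_registry(50, 400, 3000), min_cases=5)
        for s in sets:
            assert set(s.case_ids).isdisjoint(s.control_ids)

    def test_binary_trait_cell_minimum(self):
        traits = pd.DataFrame({"t": [1] * 49 + [0] * 20_000})
        sets = build_analysis_sets(None, traits=traits, trait_kinds={"t": "binary"}, trait_min_n=100)
        assert not sets[0].included
        assert "50" in sets[0].reason

    def test_small_trait_excluded(self):
        traits = pd.DataFrame({"t": np.arange(500, dtype=float)})
        sets = build_analysis_sets(None, traits=traits, trait_min_n=10_000)
        assert not sets[0].included and sets[0].reason == "n<10000"


@pytest.fixture(scope="module")
def scan_inputs():
    # two diseases so each analysis sees a clean contrast: "Dprev" has
    # near-zero incidence (the never-pool stays unselected for the logistic
    # recovery check) and "Dinc" drives incidence for the Cox check
    cfg = SimulationConfig(
        n_participants=6000,
        n_metabolites=4,
        disease_specs=[
            DiseaseSpec(
                "Dprev", mode="hazard_driven", incidence_scale=1e-4,
                prevalence_prevalent=0.08, effect_metabolites=[[0, 0.5]],
            ),
            DiseaseSpec(
                "Dinc", mode="hazard_driven", incidence_scale=0.012,
                prevalence_prevalent=0.005, effect_metabolites=[[0, 0.5]],
            ),
        ],
        seed=9,
    )
    bundle = simulate_cohort(cfg)
    z, _ = qc_transform(bundle.metabolites)
    cov, _ = impute_covariates(bundle.participants)
    sets = build_analysis_sets(bundle.registry, min_cases=50)
    return bundle, z, cov, sets


class TestScan:
    def test_planted_logistic_effect_recovered(self, scan_inputs):
        _, z, cov, sets = scan_inputs
        prev = [s for s in sets if s.kind == "prevalent"]
        recs = scan_associations(z[["met_000"]], prev, cov)
        r = recs[0]
        assert not r.failed
        # planted log-OR 0.5 per SD should sit inside the fitted 95% CI
        lo, hi = np.log(r.ci95[0]), np.log(r.ci95[1])
        assert lo < 0.5 < hi

    def test_cox_effect_recovered(self, scan_inputs):
        _, z, cov, sets = scan_inputs
        inc = [s for s in sets if s.kind == "incident"]
        recs = scan_associations(z[["met_000", "met_001"]], inc, cov)
        effects = {r.metabolite_id: r for r in recs}
        r = effects["met_000"]
        assert r.model_kind == "cox"
        assert r.effect - 3 * r.se < 0.5 < r.effect + 3 * r.se
        null = effects["met_001"]
        assert abs(null.effect) < 3 * null.se

    def test_ci_reproduces_from_effect_and_se(self, scan_inputs):
        _, z, cov, sets = scan_inputs
        recs = scan_associations(z, [s for s in sets if s.kind == "prevalent"], cov)
        for r in recs:
            assert np.exp(r.effect - 1.96 * r.se) == pytest.approx(r.ci95[0], abs=1e-6)
            assert np.exp(r.effect + 1.96 * r.se) == pytest.approx(r.ci95[1], abs=1e-6)
            assert 0 < r.p_value <= 1

    def test_row_order_invariance(self, scan_inputs):
        _, z, cov, sets = scan_inputs
        prev = [s for s in sets if s.kind == "prevalent"]
        recs1 = scan_associations(z[["met_000"]], prev, cov)
        perm = np.random.default_rng(0).permutation(len(z))
        recs2 = scan_associations(z.iloc[perm][["met_000"]], prev, cov.iloc[perm])
        assert recs1[0].effect == pytest.approx(recs2[0].effect, abs=1e-8)
        assert recs1[0].p_value == pytest.approx(recs2[0].p_value, rel=1e-6)

    def test_binary_trait_reversed_orientation(self, scan_inputs):
        bundle, z, cov, _ = scan_inputs
        rng = np.random.default_rng(1)
        traits = pd.DataFrame(
            {"tb": rng.integers(0, 2, len(z))}, index=z.index
        )
        sets = build_analysis_sets(None, traits=traits, trait_kinds={"tb": "binary"}, trait_min_n=100)
        recs = scan_associations(z[["met_000"]], sets, cov)
        assert recs[0].model_kind == "linear"
        assert recs[0].orientation == "metabolite~trait"

    def test_continuous_and_ordinal_traits_fit(self, scan_inputs):
        bundle, z, cov, _ = scan_inputs
        rng = np.random.default_rng(2)
        traits = pd.DataFrame(
            {
                "tc": z["met_001"] * 0.5 + rng.standard_normal(len(z)),
                "to": rng.integers(1, 5, len(z)),
            },
            index=z.index,
        )
        sets = build_analysis_sets(
            None, traits=traits, trait_kinds={"tc": "continuous", "to": "ordinal"}, trait_min_n=100
        )
        recs = scan_associations(z[["met_001"]], sets, cov)
        by_phen = {r.phenotype_id: r for r in recs}
        assert by_phen["tc"].model_kind == "linear" and by_phen["tc"].p_value < 1e-10
        assert by_phen["to"].model_kind == "ordinal_logistic" and not by_phen["to"].failed

    def test_failed_fit_reported_not_dropped(self, scan_inputs):
        _, z, cov, sets = scan_inputs
        # complete separation: constant-ish metabolite equal to case status
        prev = [s for s in sets if s.kind == "prevalent"]
        sep = z[["met_000"]].copy()
        case_set = set(prev[0].case_ids)
        sep["met_000"] = [100.0 if i in case_set else -100.0 for i in sep.index]
        recs = scan_associations(sep, prev, cov)
        assert len(recs) == 1  # still one record per metabolite x phenotype


class TestSubgroups:
    def test_sex_stratified_design_has_no_sex_column(self, scan_inputs):
        _, z, cov, _ = scan_inputs
        X = build_design(cov, drop=("sex",))
        assert not any("sex" in c for c in X.columns)

    def test_divergent_pair_flagged(self):
        # planted opposite sex-specific effects via direct construction
        rng = np.random.default_rng(3)
        n = 12_000
        ids = pd.Index([f"P{i:05d}" for i in range(n)], name="participant_id")
        sex = np.where(rng.random(n) < 0.5, "female", "male")
        met = rng.standard_normal(n)
        lin = np.where(sex == "female", -0.7, 0.7) * met - 1.8
        y = rng.random(n) < 1 / (1 + np.exp(-lin))
        cov = pd.DataFrame(
            {
                "age": rng.uniform(40, 70, n),
                "sex": sex,
                "tdi": rng.normal(0, 3, n),
                "bmi": rng.normal(27, 4, n),
                "smoking": rng.choice(["never", "former", "current"], n),
                "statin": rng.integers(0, 2, n),
                "fasting_time": rng.gamma(4, 1, n),
            },
            index=ids,
        )
        z = pd.DataFrame({"met_000": met}, index=ids)
        registry = pd.DataFrame(
            {
                "participant_id": ids,
                "disease_id": "D",
                "status": np.where(y, "prevalent", "never"),
                "onset_time": np.nan,
                "censor_time": 15.0,
            }
        )
        sets = [s for s in build_analysis_sets(registry, min_cases=50) if s.kind == "prevalent"]
        records, divergent, interactions = subgroup_and_interaction(
            z, sets, cov, min_cases=50
        )
        assert any(
            d["metabolite_id"] == "met_000" and d["strata"] == ("female", "male")
            for d in divergent
        )
        ix = [i for i in interactions if i["modifier"] == "sex"]
        assert ix and ix[0]["p_value"] < 1e-6

    def test_stratum_labels_present(self, scan_inputs):
        _, z, cov, sets = scan_inputs
        prev = [s for s in sets if s.kind == "prevalent"]
        records, _, _ = subgroup_and_interaction(z[["met_000"]], prev, cov, min_cases=20)
        labels = {r.stratum for r in records}
        assert labels == {"female", "male", "age<60", "age>=60"}


class TestReplication:
    def test_bh_examples(self, scan_inputs):
        _, z, cov, sets = scan_inputs
        prev = [s for s in sets if s.kind == "prevalent"]
        derivation = scan_associations(z[["met_000"]], prev, cov)
        for r in derivation:
            r.passes_bonferroni = True  # force into replication family
        rep_records = replicate_fdr(derivation, z[["met_000"]], prev, cov)
        assert len(rep_records) == len(derivation)
        assert derivation[0].replication_p is not None
        assert derivation[0].passes_fdr in (True, False)

    def test_unavailable_pair_excluded_from_family(self, scan_inputs):
        _, z, cov, sets = scan_inputs
        prev = [s for s in sets if s.kind == "prevalent"]
        derivation = scan_associations(z[["met_000"]], prev, cov)
        derivation[0].passes_bonferroni = True
        rep_records = replicate_fdr(derivation, z[["met_000"]], [], cov)
        assert rep_records[0].failed and rep_records[0].diagnostic == "unavailable"
        assert derivation[0].passes_fdr is None


def test_cox_agrees_with_exponential_regression_oracle():
    # no censoring, exponential times: the Cox log-HR should sit within
    # 3 SE of the closed-form exponential-regression MLE (Poisson GLM with
    # log-time offset) at n=5,000
    import statsmodels.api as sm
    from lifelines import CoxPHFitter

    rng = np.random.default_rng(8)
    n = 5000
    x = rng.standard_normal(n)
    beta = 0.4
    times = rng.exponential(1.0, n) / (0.1 * np.exp(beta * x))
    frame = pd.DataFrame({"x": x, "_duration": times, "_event": 1})
    cph = CoxPHFitter()
    cph.fit(frame, duration_col="_duration", event_col="_event")
    glm = sm.GLM(
        np.ones(n), sm.add_constant(x), family=sm.families.Poisson(),
        offset=np.log(times),
    ).fit()
    oracle = glm.params[1]
    assert abs(cph.params_["x"] - oracle) < 3 * cph.standard_errors_["x"]


def test_records_to_frame_columns(scan_inputs):
    _, z, cov, sets = scan_inputs
    recs = scan_associations(z[["met_000"]], [s for s in sets if s.kind == "prevalent"], cov)
    frame = records_to_frame(recs)
    assert {"metabolite_id", "phenotype_id", "effect", "p_value", "passes_bonferroni"} <= set(
        frame.columns
    )
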