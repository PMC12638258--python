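"""Nested case-control matching, timeframe profiling, backward screening."""

import numpy as np
import pandas as pd
import pytest

from metaphenome._stats import ward_silhouette_k
from metaphenome.preonset import (
    MatchedSet,
    TimeframeProfile,
    assign_bin,
    backward_screen,
    cluster_trajectories,
    propensity_match,
    timeframe_profile,
)
from metaphenome.preprocess import impute_covariates, qc_transform
from metaphenome.synthcohort import (
    DiseaseSpec,
    DivergenceSpec,
    SimulationConfig,
    simulate_cohort,
)


def _covariates(rng, n, index=None):
    ids = index if index is not None else pd.Index(
        [f"P{i:05d}" for i in range(n)], name="participant_id"
    )
    return pd.DataFrame(
        {
            "sex": rng.choice(["female", "male"], n),
            "age": rng.uniform(40, 70, n),
            "ethnicity": rng.choice(["white", "other"], n, p=[0.95, 0.05]),
            "bmi": rng.normal(27, 4, n),
            "tdi": rng.normal(0, 3, n),
            "smoking": rng.choice(["never", "former", "current"], n),
            "statin": rng.integers(0, 2, n),
            "fasting_time": rng.gamma(4, 1, n),
        },
        index=ids,
    )


class TestMatching:
    def test_identical_covariates_matched_at_zero_distance(self, rng):
        pool = _covariates(rng, 200)
        case = pool.iloc[[0]].copy()
        case.index = pd.Index(["CASE0"], name="participant_id")
        onset = pd.Series([3.0], index=case.index)
        sets = propensity_match(case, pool, onset, ratio=1, seed=0)
        assert sets[0].distances[0] == pytest.approx(0.0, abs=1e-12)
        assert sets[0].control_ids[0] == pool.index[0]

    def test_ratio_honoured_with_ample_pool(self, rng):
        cov = _covariates(rng, 1100)
        cases, pool = cov.iloc[:100], cov.iloc[100:]
        onset = pd.Series(rng.uniform(1, 10, 100), index=cases.index)
        sets = propensity_match(cases, pool, onset, ratio=5, seed=1)
        assert all(len(s.control_ids) == 5 for s in sets)

    def test_without_replacement(self, rng):
        cov = _covariates(rng, 600)
        cases, pool = cov.iloc[:100], cov.iloc[100:]
        onset = pd.Series(rng.uniform(1, 10, 100), index=cases.index)
        sets = propensity_match(cases, pool, onset, ratio=5, seed=2)
        used = [c for s in sets for c in s.control_ids]
        assert len(used) == len(set(used))
        assert all(s.case_id not in s.control_ids for s in sets)

    def test_controls_inherit_proxy_time(self, rng):
        cov = _covariates(rng, 60)
        cases, pool = cov.iloc[:5], cov.iloc[5:]
        onset = pd.Series([1.5, 2.5, 3.5, 4.5, 5.5], index=cases.index)
        sets = propensity_match(cases, pool, onset, ratio=2, seed=0)
        by_case = {s.case_id: s for s in sets}
        for cid, t in onset.items():
            assert by_case[str(cid)].proxy_time == t

    def test_balance_on_confounded_cohort(self):
        # cases drawn preferentially at high BMI/age: matching should bring
        # standardized mean differences of the matching covariates under 0.1
        rng = np.random.default_rng(5)
        n = 20_000
        cov = _covariates(rng, n)
        score = 0.08 * (cov["bmi"] - 27) + 0.05 * (cov["age"] - 55)
        p_case = 1 / (1 + np.exp(-(score - 3.2)))
        is_case = rng.random(n) < p_case
        cases, pool = cov[is_case], cov[~is_case]
        onset = pd.Series(rng.uniform(1, 14, is_case.sum()), index=cases.index)
        sets = propensity_match(cases, pool, onset, ratio=5, seed=3)
        ctrl_ids = [c for s in sets for c in s.control_ids]
        for col in ("bmi", "age", "tdi"):
            pooled_sd = np.sqrt((cases[col].var() + pool[col].var()) / 2)
            smd = abs(cases[col].mean() - cov.loc[ctrl_ids, col].mean()) / pooled_sd
            assert smd < 0.1, col

    def test_deficit_logged_when_pool_small(self, rng, caplog):
        cov = _covariates(rng, 30)
        cases, pool = cov.iloc[:10], cov.iloc[10:]
        onset = pd.Series(rng.uniform(1, 5, 10), index=cases.index)
        with caplog.at_level("WARNING"):
            sets = propensity_match(cases, pool, onset, ratio=5, seed=0)
        assert sum(len(s.control_ids) for s in sets) == 20
        assert "deficit" in caplog.text


class TestTimeframeProfile:
    def test_bin_convention(self):
        assert assign_bin(4.5) == 5
        assert assign_bin(4.0) == 4
        assert assign_bin(0.2) == 1

    def test_planted_step_shift_recovered(self):
        # +1 SD shift for time-to-onset <= 3 yr; 400 cases/bin keeps the
        # per-bin z SE (~0.054) well inside the 0.15 tolerance
        rng = np.random.default_rng(3)
        n_bins, per_bin, ratio = 15, 400, 5
        n_cases = n_bins * per_bin
        n_ctrl = n_cases * ratio
        case_ids = [f"C{i:05d}" for i in range(n_cases)]
        ctrl_ids = [f"N{i:05d}" for i in range(n_ctrl)]
        t_onset = np.repeat(np.arange(1, n_bins + 1) - 0.5, per_bin)
        met = rng.standard_normal(n_cases + n_ctrl)
        met[:n_cases] += (t_onset <= 3).astype(float)
        ids = pd.Index(case_ids + ctrl_ids, name="participant_id")
        z = pd.DataFrame({"met": met}, index=ids)
        cov = _covariates(rng, len(ids), index=ids)
        sets = []
        for i, cid in enumerate(case_ids):
            sets.append(
                MatchedSet(
                    case_id=cid,
                    control_ids=ctrl_ids[i * ratio : (i + 1) * ratio],
                    proxy_time=float(t_onset[i]),
                    distances=[0.0] * ratio,
                )
            )
        profile = timeframe_profile(sets, z, cov)[0]
        assert np.all(np.abs(profile.z[:3] - 1.0) < 0.15)
        assert np.all(np.abs(profile.z[3:]) < 0.15)
        assert profile.available.all()

    def test_null_profile_is_flat(self):
        rng = np.random.default_rng(12)
        n_cases, ratio = 1500, 3
        case_ids = [f"C{i:05d}" for i in range(n_cases)]
        ctrl_ids = [f"N{i:05d}" for i in range(n_cases * ratio)]
        ids = pd.Index(case_ids + ctrl_ids, name="participant_id")
        z = pd.DataFrame({"met": rng.standard_normal(len(ids))}, index=ids)
        cov = _covariates(rng, len(ids), index=ids)
        sets = [
            MatchedSet(
                case_id=cid,
                control_ids=ctrl_ids[i * ratio : (i + 1) * ratio],
                proxy_time=float(rng.uniform(0.01, 15.0)),
                distances=[0.0] * ratio,
            )
            for i, cid in enumerate(case_ids)
        ]
        profile = timeframe_profile(sets, z, cov)[0]
        from scipy import stats as sps

        avail = profile.available
        assert abs(np.nanmean(profile.z[avail])) < 0.05
        assert sps.kstest(profile.p[avail], "uniform").pvalue > 0.01

    def test_small_bin_marked_unavailable(self, rng):
        ids = pd.Index([f"C{i}" for i in range(5)] + [f"N{i}" for i in range(25)],
                       name="participant_id")
        z = pd.DataFrame({"met": rng.standard_normal(30)}, index=ids)
        cov = _covariates(rng, 30, index=ids)
        sets = [
            MatchedSet(case_id=f"C{i}", control_ids=[f"N{j}" for j in range(i * 5, i * 5 + 5)],
                       proxy_time=1.5, distances=[0.0] * 5)
            for i in range(5)
        ]
        profile = timeframe_profile(sets, z, cov, min_cases_per_bin=10)[0]
        assert not profile.available.any()
        assert np.isnan(profile.z).all()

    def test_order_invariance(self, rng):
        n_cases, ratio = 300, 2
        case_ids = [f"C{i:04d}" for i in range(n_cases)]
        ctrl_ids = [f"N{i:04d}" for i in range(n_cases * ratio)]
        ids = pd.Index(case_ids + ctrl_ids, name="participant_id")
        z = pd.DataFrame({"met": rng.standard_normal(len(ids))}, index=ids)
        cov = _covariates(rng, len(ids), index=ids)
        sets = [
            MatchedSet(case_id=cid, control_ids=ctrl_ids[i * ratio : (i + 1) * ratio],
                       proxy_time=float((i % 15) + 0.5), distances=[0.0] * ratio)
            for i, cid in enumerate(case_ids)
        ]
        p1 = timeframe_profile(sets, z, cov)[0]
        p2 = timeframe_profile(list(reversed(sets)), z, cov)[0]
        np.testing.assert_allclose(p1.z, p2.z, equal_nan=True)
        np.testing.assert_allclose(p1.p, p2.p, equal_nan=True)


def _profile(p_sequence, disease="D", met="m"):
    p = np.asarray(p_sequence, dtype=float)
    return TimeframeProfile(
        disease_id=disease,
        metabolite_id=met,
        n_bins=len(p),
        z=np.zeros(len(p)),
        p=p,
        n_cases=np.full(len(p), 50),
        available=~np.isnan(p),
    )


class TestBackwardScreen:
    def test_all_significant_gives_final_bin(self):
        call = backward_screen(_profile([0.001] * 15))
        assert call.emergence_bin == 15

    def test_example_sequence_stopping_vs_last_significant(self):
        p = [0.001, 0.3, 0.001, 0.4, 0.6, 0.5] + [0.5] * 9
        assert backward_screen(_profile(p)).emergence_bin == 4
        assert (
            backward_screen(_profile(p), convention="last_significant").emergence_bin == 3
        )

    def test_immediate_stop_is_none(self):
        call = backward_screen(_profile([0.2, 0.3] + [0.5] * 13))
        assert call.emergence_bin is None

    def test_unavailable_bins_count_as_non_significant(self):
        p = [0.001, np.nan, np.nan] + [0.001] * 12
        assert backward_screen(_profile(p)).emergence_bin == 2

    def test_all_unavailable_errors(self):
        with pytest.raises(ValueError, match="unavailable"):
            backward_screen(_profile([np.nan] * 15))

    def test_single_trailing_nonsignificant_not_a_stop(self):
        # bins 1..14 significant, bin 15 not: no consecutive pair -> B
        p = [0.001] * 14 + [0.5]
        assert backward_screen(_profile(p)).emergence_bin == 15


class TestClusterTrajectories:
    def test_duplicate_matrices_share_label(self, rng):
        base = rng.standard_normal((10, 15))
        mats = {"A": base, "B": base.copy(), "C": base + 8.0, "D": base - 8.0}
        result = cluster_trajectories(mats, k_range=range(2, 4))
        by = dict(zip(result.disease_ids, result.labels))
        assert by["A"] == by["B"]

    def test_two_planted_families_perfectly_split(self, rng):
        mats = {}
        for i in range(6):
            mats[f"up{i}"] = rng.standard_normal((8, 15)) * 0.1 + 5.0
            mats[f"dn{i}"] = rng.standard_normal((8, 15)) * 0.1 - 5.0
        result = cluster_trajectories(mats, k_range=range(2, 6))
        assert result.chosen_k == 2
        groups = {}
        for d, lbl in zip(result.disease_ids, result.labels):
            groups.setdefault(d[:2], set()).add(lbl)
        assert groups["up"].isdisjoint(groups["dn"])
        assert len(groups["up"]) == len(groups["dn"]) == 1

    def test_chosen_k_is_silhouette_argmax(self, rng):
        mats = {f"d{i}": rng.standard_normal((5, 15)) + (i % 3) * 6 for i in range(12)}
        result = cluster_trajectories(mats, k_range=range(2, 7))
        _, scores, k = ward_silhouette_k(result.matrix, range(2, 7))
        assert result.chosen_k == k == max(scores, key=lambda kk: (scores[kk], -kk))

    def test_nan_cells_imputed_and_counted(self, rng):
        base = rng.standard_normal((4, 15))
        withnan = base.copy()
        withnan[0, 0] = np.nan
        mats = {"A": withnan, "B": base + 5, "C": base - 5}
        result = cluster_trajectories(mats, k_range=range(2, 3))
        assert result.imputed == {"A": 1}

    def test_fewer_than_three_diseases_errors(self, rng):
        with pytest.raises(ValueError, match="3 diseases"):
            cluster_trajectories({"A": rng.standard_normal((3, 15)),
                                  "B": rng.standard_normal((3, 15))})


class TestEndToEndEmergence:
    def test_planted_linear_ramp_recovered_within_one_bin(self):
        # single replicate of the acceptance-style recovery at reduced size
        cfg = SimulationConfig(
            n_participants=16_000,
            n_metabolites=2,
            disease_specs=[
                DiseaseSpec(
                    "D", mode="divergence_driven", incidence_scale=0.011,
                    divergence=DivergenceSpec(
                        metabolite=0, emergence_time=10.0, shift=0.8, ramp="linear"
                    ),
                )
            ],
            seed=21,
        )
        bundle = simulate_cohort(cfg)
        z, _ = qc_transform(bundle.metabolites)
        cov, _ = impute_covariates(bundle.participants)
        reg = bundle.registry.set_index("participant_id")
        cases = reg.index[reg["status"] == "incident"]
        pool = reg.index[reg["status"] == "never"]
        sets = propensity_match(
            cov.loc[cases], cov.loc[pool], reg.loc[cases, "onset_time"], seed=0
        )
        profile = timeframe_profile(sets, z[["met_000"]], cov)[0]
        call = backward_screen(profile)
        assert call.emergence_bin is not None
        assert abs(call.emergence_bin - 10) <= 1
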