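"""Nested case-control construction and pre-onset divergence estimation.

Cases are matched to controls on a propensity score (logistic model of
case status on sex, age, ethnicity, BMI and TDI) by nearest neighbour
without replacement; each control inherits the case's time-to-onset as a
proxy time.  Time-to-onset is binned into B one-year bins (bin b covers
(b-1, b] years), case/control contrasts are summarized per bin as a z
statistic and Welch-test p value, and a backward screen walking outward
from onset stops at the first two consecutive non-significant bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression

from ._stats import ward_silhouette_k

logger = logging.getLogger(__name__)

__all__ = [
    "MatchedSet",
    "TimeframeProfile",
    "EmergenceCall",
    "TrajectoryClusterResult",
    "propensity_match",
    "timeframe_profile",
    "backward_screen",
    "cluster_trajectories",
]

MATCH_COVARIATES = ["sex", "age", "ethnicity", "bmi", "tdi"]


@dataclass
class MatchedSet:
    case_id: str
    control_ids: list
    proxy_time: float  # case's years to onset, inherited by its controls
    distances: list


@dataclass
class TimeframeProfile:
    disease_id: str
    metabolite_id: str
    n_bins: int
    z: np.ndarray  # per-bin z, NaN where unavailable
    p: np.ndarray  # per-bin Welch p, NaN where unavailable
    n_cases: np.ndarray
    available: np.ndarray  # bool per bin
    adjustment_covariates: tuple = ("smoking", "statin", "fasting_time")


@dataclass
class EmergenceCall:
    disease_id: str
    metabolite_id: str
    emergence_bin: Optional[int]  # 1..B, or None if screening stops at bin 1
    convention: str  # stopping_bin | last_significant
    p_sequence: np.ndarray


@dataclass
class TrajectoryClusterResult:
    disease_ids: list
    matrix: np.ndarray  # diseases x (metabolites*bins), smoothed
    labels: np.ndarray  # 1..k
    chosen_k: int
    silhouette: dict  # k -> mean silhouette
    imputed: dict = field(default_factory=dict)  # disease -> #cells imputed as 0


# -- matching ---------------------------------------------------------------


def propensity_match(
    cases: pd.DataFrame,
    pool: pd.DataFrame,
    onset_times: pd.Series,
    covariates: list[str] | None = None,
    ratio: int = 5,
    seed: int = 0,
) -> list[MatchedSet]:
    """Nearest-neighbour propensity matching without replacement.

    ``cases``/``pool`` are covariate tables indexed by participant id;
    ``onset_times`` gives each case's time to onset.  Cases are processed
    in a seed-randomized order; each draws up to ``ratio`` nearest unused
    pool members by propensity-score distance.  Deficits are logged.
    """
    covariates = covariates or MATCH_COVARIATES
    rng = np.random.default_rng(seed)
    both = pd.concat([cases[covariates], pool[covariates]])
    y = np.r_[np.ones(len(cases)), np.zeros(len(pool))]
    X = pd.get_dummies(both, drop_first=True, dtype=float).to_numpy(float)
    # lightly ridge-stabilized logistic: robust to separation/tiny case
    # counts, and matching only consumes the score ordering
    model = LogisticRegression(C=100.0, max_iter=1000)
    model.fit(X, y)
    scores = model.predict_proba(X)[:, 1]
    case_scores = scores[: len(cases)]
    pool_scores = scores[len(cases) :]

    order = np.argsort(pool_scores, kind="mergesort")
    sorted_scores = pool_scores[order]
    sorted_ids = np.asarray(pool.index)[order]
    used = np.zeros(len(pool), dtype=bool)

    sets: list[MatchedSet] = []
    case_order = rng.permutation(len(cases))
    total_deficit = 0
    for ci in case_order:
        cs = case_scores[ci]
        picked_idx: list[int] = []
        picked_dist: list[float] = []
        pos = int(np.searchsorted(sorted_scores, cs))
        lo, hi = pos - 1, pos
        while len(picked_idx) < ratio and (lo >= 0 or hi < len(sorted_scores)):
            # advance each cursor past used entries
            while lo >= 0 and used[lo]:
                lo -= 1
            while hi < len(sorted_scores) and used[hi]:
                hi += 1
            d_lo = cs - sorted_scores[lo] if lo >= 0 else np.inf
            d_hi = sorted_scores[hi] - cs if hi < len(sorted_scores) else np.inf
            if d_lo == np.inf and d_hi == np.inf:
                break
            if d_lo <= d_hi:
                picked_idx.append(lo)
                picked_dist.append(float(d_lo))
                used[lo] = True
                lo -= 1
            else:
                picked_idx.append(hi)
                picked_dist.append(float(d_hi))
                used[hi] = True
                hi += 1
        if len(picked_idx) < ratio:
            total_deficit += ratio - len(picked_idx)
        case_id = cases.index[ci]
        sets.append(
            MatchedSet(
                case_id=str(case_id),
                control_ids=[str(sorted_ids[i]) for i in picked_idx],
                proxy_time=float(onset_times.loc[case_id]),
                distances=picked_dist,
            )
        )
    if total_deficit:
        logger.warning("matching deficit: %d controls short of ratio %d", total_deficit, ratio)
    sets.sort(key=lambda s: s.case_id)
    return sets


# -- per-timeframe profiling ------------------------------------------------


def assign_bin(time_to_onset: float) -> int:
    """Bin b covers time-to-onset in (b-1, b] years (so 4.5 yr -> bin 5)."""
    return int(np.ceil(time_to_onset))


def timeframe_profile(
    matched_sets: list[MatchedSet],
    z_metabolites: pd.DataFrame,
    covariates: pd.DataFrame,
    disease_id: str = "",
    n_bins: int = 15,
    min_cases_per_bin: int = 10,
    adjustment: tuple = ("smoking", "statin", "fasting_time"),
    denominator: str = "sd",
) -> list[TimeframeProfile]:
    """Per-bin case-control contrast for every metabolite column.

    Within each bin, metabolite values are adjusted by regressing out the
    adjustment covariates (model fitted on that bin's controls only, then
    applied to everyone in the bin); z_b is the adjusted case mean minus
    control mean over the adjusted control SD (or variance when
    ``denominator='variance'``), and p_b is a two-sided Welch t-test.
    """
    if denominator not in ("sd", "variance"):
        raise ValueError("denominator must be 'sd' or 'variance'")
    bins_cases: dict[int, list] = {b: [] for b in range(1, n_bins + 1)}
    bins_controls: dict[int, list] = {b: [] for b in range(1, n_bins + 1)}
    for ms in sorted(matched_sets, key=lambda s: s.case_id):
        b = assign_bin(ms.proxy_time)
        if b < 1 or b > n_bins:
            logger.info("case %s with time-to-onset %.2f outside profiling window", ms.case_id, ms.proxy_time)
            continue
        bins_cases[b].append(ms.case_id)
        bins_controls[b].extend(ms.control_ids)

    adj_cols = [c for c in adjustment if c in covariates.columns]
    design_all = pd.get_dummies(covariates[adj_cols], drop_first=True, dtype=float)

    mets = list(z_metabolites.columns)
    z_mat = np.full((len(mets), n_bins), np.nan)
    p_mat = np.full((len(mets), n_bins), np.nan)
    n_mat = np.zeros((len(mets), n_bins), dtype=int)
    avail = np.zeros((len(mets), n_bins), dtype=bool)

    for b in range(1, n_bins + 1):
        case_ids = [i for i in bins_cases[b] if i in z_metabolites.index]
        ctrl_ids = [i for i in bins_controls[b] if i in z_metabolites.index]
        if len(case_ids) < min_cases_per_bin or len(ctrl_ids) < 2:
            continue
        Xc = sm.add_constant(design_all.loc[ctrl_ids], has_constant="add").to_numpy(float)
        Xa = sm.add_constant(
            design_all.loc[case_ids + ctrl_ids], has_constant="add"
        ).to_numpy(float)
        Yc = z_metabolites.loc[ctrl_ids].to_numpy(float)
        Ya = z_metabolites.loc[case_ids + ctrl_ids].to_numpy(float)
        nc = len(case_ids)
        for j in range(len(mets)):
            # metabolite values can be missing (QC outlier masking): fit the
            # control-only adjustment on complete rows, column by column
            yc = Yc[:, j]
            ya = Ya[:, j]
            ok_c = ~np.isnan(yc)
            ok_a = ~np.isnan(ya)
            if ok_c.sum() < Xc.shape[1] + 1 or ok_a[:nc].sum() < min_cases_per_bin:
                continue
            beta, *_ = np.linalg.lstsq(Xc[ok_c], yc[ok_c], rcond=None)
            resid = ya - Xa @ beta
            res_cases = resid[:nc][ok_a[:nc]]
            res_ctrls = resid[nc:][ok_a[nc:]]
            if res_ctrls.size < 2:
                continue
            ctrl_sd = res_ctrls.std(ddof=1)
            denom = ctrl_sd if denominator == "sd" else ctrl_sd**2
            if denom <= 0:
                continue
            zb = (res_cases.mean() - res_ctrls.mean()) / denom
            pb = sps.ttest_ind(res_cases, res_ctrls, equal_var=False).pvalue
            if np.isfinite(zb) and np.isfinite(pb):
                z_mat[j, b - 1] = zb
                p_mat[j, b - 1] = pb
                n_mat[j, b - 1] = res_cases.size
                avail[j, b - 1] = True

    return [
        TimeframeProfile(
            disease_id=disease_id,
            metabolite_id=met,
            n_bins=n_bins,
            z=z_mat[j],
            p=p_mat[j],
            n_cases=n_mat[j],
            available=avail[j],
            adjustment_covariates=tuple(adj_cols),
        )
        for j, met in enumerate(mets)
    ]


# -- backward screening -----------------------------------------------------


def backward_screen(
    profile: TimeframeProfile, alpha: float = 0.05, convention: str = "stopping_bin"
) -> EmergenceCall:
    """Walk bins outward from onset; stop at two consecutive p > alpha.

    Unavailable bins count as non-significant.  With stop index b*:
    emergence is b* (``stopping_bin``) or b*-1 (``last_significant``);
    b* = 1 means no emergence; no stop through bin B means emergence = B.
    """
    if convention not in ("stopping_bin", "last_significant"):
        raise ValueError("convention must be 'stopping_bin' or 'last_significant'")
    if not profile.available.any():
        raise ValueError(
            f"all bins unavailable for {profile.disease_id}/{profile.metabolite_id}"
        )
    B = profile.n_bins
    nonsig = np.array(
        [(not profile.available[b]) or profile.p[b] > alpha for b in range(B)]
    )
    b_star = None
    for b in range(B - 1):
        if nonsig[b] and nonsig[b + 1]:
            b_star = b + 1  # 1-based
            break
    if b_star is None:
        emergence: Optional[int] = B
    elif b_star == 1:
        emergence = None
    else:
        emergence = b_star if convention == "stopping_bin" else b_star - 1
    return EmergenceCall(
        disease_id=profile.disease_id,
        metabolite_id=profile.metabolite_id,
        emergence_bin=emergence,
        convention=convention,
        p_sequence=profile.p.copy(),
    )


# -- trajectory clustering --------------------------------------------------


def _smooth_series(y: np.ndarray, frac: float) -> np.ndarray:
    """LOWESS over bin index (local linear, tricube weights)."""
    from statsmodels.nonparametric.smoothers_lowess import lowess

    x = np.arange(len(y), dtype=float)
    return lowess(y, x, frac=frac, xvals=x)


def cluster_trajectories(
    profile_matrices: dict[str, np.ndarray],
    smoothing_frac: float = 0.5,
    k_range: range | None = None,
) -> TrajectoryClusterResult:
    """Ward/Euclidean clustering of per-disease metabolite-by-bin matrices.

    Each metabolite's bin series is LOWESS-smoothed, matrices are
    flattened, and k is chosen by maximum mean silhouette over
    ``k_range`` (default 2..min(60, n_diseases - 1)).  Unavailable cells
    (NaN) are imputed as 0 and counted per disease.
    """
    disease_ids = sorted(profile_matrices)
    if len(disease_ids) < 3:
        raise ValueError("need at least 3 diseases to cluster")
    rows = []
    imputed = {}
    for d in disease_ids:
        mat = np.asarray(profile_matrices[d], dtype=float).copy()
        n_nan = int(np.isnan(mat).sum())
        if n_nan:
            imputed[d] = n_nan
            mat = np.nan_to_num(mat, nan=0.0)
        smoothed = np.vstack([_smooth_series(row, smoothing_frac) for row in mat])
        rows.append(smoothed.ravel())
    matrix = np.vstack(rows)
    if k_range is None:
        k_range = range(2, min(60, len(disease_ids) - 1) + 1)
    labels, scores, k = ward_silhouette_k(matrix, k_range)
    if imputed:
        logger.info("imputed-as-zero cells: %s", imputed)
    return TrajectoryClusterResult(
        disease_ids=disease_ids,
        matrix=matrix,
        labels=labels,
        chosen_k=k,
        silhouette=scores,
        imputed=imputed,
    )


def profiles_to_frame(profiles: list[TimeframeProfile]) -> pd.DataFrame:
    """Long-format table: disease, metabolite, bin, z, p, n_cases, available."""
    rows = []
    for pr in profiles:
        for b in range(pr.n_bins):
            rows.append(
                {
                    "disease_id": pr.disease_id,
                    "metabolite_id": pr.metabolite_id,
                    "bin": b + 1,
                    "z": pr.z[b],
                    "p": pr.p[b],
                    "n_cases": pr.n_cases[b],
                    "available": bool(pr.available[b]),
                }
            )
    return pd.DataFrame(rows)
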