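"""Age-trend curves, metabolite clustering across age, and sliding-window
ageing-wave quantification.

The sliding-window scan centres a window at each integer age, pools the
parcel of individuals just below ([c-w, c)) and just above ([c, c+w)) the
centre, and fits, per metabolite,

    metabolite ~ intercept + beta1 * age_group + beta2 * sex + beta3 * ethnicity

recording beta1, its p value, a Benjamini-Hochberg q within the centre,
and the signed score sign(beta1) * (-log10 p).  Counts of metabolites
below each q threshold trace the "waves"; their interior local maxima are
the crest ages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.nonparametric.smoothers_lowess import lowess

from ._stats import bh_adjust, ward_silhouette_k

logger = logging.getLogger(__name__)

__all__ = [
    "AgeCurve",
    "DeswanResult",
    "WavePeaks",
    "age_adjusted_curves",
    "cluster_age_curves",
    "deswan_scan",
    "detect_wave_peaks",
]

DEFAULT_Q_THRESHOLDS = (0.0001, 0.001, 0.01, 0.05)
ADJUST_COVARIATES = ["sex", "ethnicity", "tdi", "bmi", "smoking", "statin", "fasting_time"]


@dataclass
class AgeCurve:
    metabolite_id: str
    grid: np.ndarray
    fitted: np.ndarray
    span: float


@dataclass
class DeswanResult:
    centres: np.ndarray
    width: int
    metabolite_ids: list
    beta1: np.ndarray  # centres x metabolites
    p: np.ndarray
    q: np.ndarray
    signed_score: np.ndarray  # sign(beta1) * -log10(p)
    counts: dict  # q threshold -> array over centres
    q_thresholds: tuple = DEFAULT_Q_THRESHOLDS
    failed: list = field(default_factory=list)  # (centre, reason) or (centre, met, reason)


@dataclass
class WavePeaks:
    q_threshold: float
    peak_ages: list
    peak_counts: list


# -- age curves -------------------------------------------------------------


def age_adjusted_curves(
    z_metabolites: pd.DataFrame,
    covariates: pd.DataFrame,
    grid: np.ndarray | None = None,
    span: float = 0.75,
    adjust: list[str] | None = None,
    min_participants: int = 100,
) -> list[AgeCurve]:
    """Residualize each metabolite on the non-age covariates, re-standardize,
    and smooth the residual against age with a local-linear LOWESS evaluated
    on the integer age grid (default 40..70)."""
    grid = np.arange(40, 71, dtype=float) if grid is None else np.asarray(grid, float)
    if adjust is None:
        adjust = ADJUST_COVARIATES
    adjust = [c for c in adjust if c in covariates.columns]
    age = covariates["age"].to_numpy(float)
    in_range = (age >= grid.min()) & (age <= grid.max())
    if in_range.sum() < min_participants:
        raise ValueError(f"only {int(in_range.sum())} participants in age range")
    ids = covariates.index[in_range]
    if adjust:
        X = pd.get_dummies(covariates.loc[ids, adjust], drop_first=True, dtype=float)
        X.insert(0, "const", 1.0)
    else:
        X = pd.DataFrame({"const": np.ones(len(ids))}, index=ids)
    Xn = X.to_numpy(float)
    Y = z_metabolites.loc[ids].to_numpy(float)
    ages = age[in_range]
    curves = []
    for j, met in enumerate(z_metabolites.columns):
        y = Y[:, j]
        ok = ~np.isnan(y)
        beta, *_ = np.linalg.lstsq(Xn[ok], y[ok], rcond=None)
        resid = y[ok] - Xn[ok] @ beta
        sd = resid.std(ddof=0) or 1.0
        resid = (resid - resid.mean()) / sd
        fitted = lowess(resid, ages[ok], frac=span, xvals=grid)
        curves.append(AgeCurve(metabolite_id=met, grid=grid, fitted=fitted, span=span))
    return curves


def cluster_age_curves(
    curves: list[AgeCurve], k_range: range | None = None
) -> tuple[np.ndarray, dict, int]:
    """Ward/Euclidean clustering of grid-evaluated curves; k by max silhouette."""
    if len(curves) < 3:
        raise ValueError("need at least 3 curves")
    matrix = np.vstack([c.fitted for c in curves])
    k_range = k_range or range(2, min(12, len(curves) - 1) + 1)
    return ward_silhouette_k(matrix, k_range)


# -- sliding-window scan ----------------------------------------------------


def _group_term_ols(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column OLS coefficient and p-value of X's second column (the
    age-group indicator), vectorized for complete columns with a
    complete-case fallback for columns containing missing values."""
    nm = Y.shape[1]
    beta = np.full(nm, np.nan)
    pvals = np.full(nm, np.nan)
    has_nan = np.isnan(Y).any(axis=0)

    def _solve(Xs: np.ndarray, Ys: np.ndarray):
        XtX_inv = np.linalg.inv(Xs.T @ Xs)
        B = XtX_inv @ Xs.T @ Ys
        resid = Ys - Xs @ B
        dof = Xs.shape[0] - Xs.shape[1]
        sigma2 = (resid**2).sum(axis=0) / dof
        se1 = np.sqrt(XtX_inv[1, 1] * sigma2)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = B[1] / se1
        return B[1], 2.0 * sps.t.sf(np.abs(tstat), dof)

    complete = ~has_nan
    if complete.any():
        beta[complete], pvals[complete] = _solve(X, Y[:, complete])
    for j in np.where(has_nan)[0]:
        ok = ~np.isnan(Y[:, j])
        if ok.sum() <= X.shape[1] + 1 or X[ok, 1].std() == 0:
            continue
        try:
            b, p = _solve(X[ok], Y[ok, j : j + 1])
        except np.linalg.LinAlgError:
            continue  # complete-case subset lost a covariate level
        beta[j], pvals[j] = b[0], p[0]
    return beta, pvals


def deswan_scan(
    z_metabolites: pd.DataFrame,
    covariates: pd.DataFrame,
    width: int = 3,
    centres: np.ndarray | None = None,
    q_thresholds: tuple = DEFAULT_Q_THRESHOLDS,
    min_parcel: int = 30,
) -> DeswanResult:
    """Sliding-window low/high age-parcel contrast per metabolite.

    Parcels at centre c are ages in [c-w, c) (low) and [c, c+w) (high);
    centres where either parcel has fewer than ``min_parcel`` individuals
    are skipped.  BH q values are computed within each centre across
    metabolites.
    """
    age = covariates["age"].to_numpy(float)
    if centres is None:
        lo = int(np.ceil(age.min())) + width - 1
        hi = int(np.floor(age.max())) - width + 1
        centres = np.arange(lo, hi + 1)
    centres = np.asarray(centres)
    mets = list(z_metabolites.columns)
    Y_all = z_metabolites.to_numpy(float)

    sex = (covariates["sex"] == "male").astype(float).to_numpy()
    eth = pd.get_dummies(covariates["ethnicity"], drop_first=True, dtype=float).to_numpy()

    nc, nm = len(centres), len(mets)
    beta1 = np.full((nc, nm), np.nan)
    pmat = np.full((nc, nm), np.nan)
    failed: list = []
    for ci, c in enumerate(centres):
        low = (age >= c - width) & (age < c)
        high = (age >= c) & (age < c + width)
        if low.sum() < min_parcel or high.sum() < min_parcel:
            failed.append((int(c), "parcel below minimum size"))
            continue
        sel = low | high
        group = high[sel].astype(float)
        X = np.column_stack([np.ones(sel.sum()), group, sex[sel], eth[sel]])
        # drop constant columns (e.g. single-ethnicity parcel) except the group term
        keep = [0, 1] + [j for j in range(2, X.shape[1]) if X[:, j].std() > 0]
        X = X[:, keep]
        if np.linalg.matrix_rank(X) < X.shape[1] or X[:, 1].std() == 0:
            failed.append((int(c), "singular design"))
            continue
        Y = Y_all[sel]
        b1, p = _group_term_ols(X, Y)
        beta1[ci] = b1
        pmat[ci] = np.clip(p, np.nextafter(0, 1), 1.0)

    qmat = np.full_like(pmat, np.nan)
    for ci in range(nc):
        if np.isfinite(pmat[ci]).any():
            qmat[ci] = bh_adjust(pmat[ci])
    with np.errstate(divide="ignore", invalid="ignore"):
        signed = np.sign(beta1) * (-np.log10(pmat))
    counts = {
        thr: np.array(
            [int(np.nansum(qmat[ci] < thr)) if np.isfinite(qmat[ci]).any() else 0 for ci in range(nc)]
        )
        for thr in q_thresholds
    }
    return DeswanResult(
        centres=centres,
        width=width,
        metabolite_ids=mets,
        beta1=beta1,
        p=pmat,
        q=qmat,
        signed_score=signed,
        counts=counts,
        q_thresholds=tuple(q_thresholds),
        failed=failed,
    )


def detect_wave_peaks(
    result: DeswanResult, q_threshold: float = 0.05
) -> WavePeaks:
    """Interior strict local maxima of the count series, plateaus merged.

    A plateau (run of equal counts) is a peak when both neighbouring runs
    are strictly lower; its reported age is the run's middle centre.
    Peaks are sorted by count descending.
    """
    counts = np.asarray(result.counts[q_threshold], dtype=float)
    centres = np.asarray(result.centres)
    if len(counts) < 5:
        raise ValueError("need a count series over at least 5 centres")
    if np.all(counts == 0):
        return WavePeaks(q_threshold=q_threshold, peak_ages=[], peak_counts=[])
    # run-length encode to merge plateaus
    runs = []  # (value, start, end inclusive)
    start = 0
    for i in range(1, len(counts) + 1):
        if i == len(counts) or counts[i] != counts[start]:
            runs.append((counts[start], start, i - 1))
            start = i
    peaks = []
    for r in range(1, len(runs) - 1):
        val, s, e = runs[r]
        if runs[r - 1][0] < val and runs[r + 1][0] < val:
            mid = (s + e) // 2
            peaks.append((int(centres[mid]), val))
    peaks.sort(key=lambda t: (-t[1], t[0]))
    return WavePeaks(
        q_threshold=q_threshold,
        peak_ages=[a for a, _ in peaks],
        peak_counts=[int(v) for _, v in peaks],
    )


def deswan_to_frame(result: DeswanResult) -> pd.DataFrame:
    """Long format: centre, metabolite, width, beta1, p, q, signed_score."""
    rows = []
    for ci, c in enumerate(result.centres):
        for mi, met in enumerate(result.metabolite_ids):
            rows.append(
                {
                    "centre": int(c),
                    "metabolite_id": met,
                    "width": result.width,
                    "beta1": result.beta1[ci, mi],
                    "p": result.p[ci, mi],
                    "q": result.q[ci, mi],
                    "signed_score": result.signed_score[ci, mi],
                }
            )
    return pd.DataFrame(rows)
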