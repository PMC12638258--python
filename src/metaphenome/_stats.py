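"""Shared statistical primitives used across analysis stages.

These are deliberately small, self-contained implementations so that the
test-suite can verify each of them against an independent brute-force
oracle (BH step-up, silhouette arg-max, rank-statistic AUC).
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import silhouette_score

__all__ = [
    "bh_adjust",
    "inverse_normal_transform",
    "auc_rank",
    "delong_test",
    "ward_silhouette_k",
]


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values).

    q_(i) = min_{j >= i} ( m * p_(j) / j ), clipped to 1.  NaN entries are
    excluded from the family and returned as NaN.
    """
    p = np.asarray(p_values, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(ranked, 0.0, 1.0)
    q[ok] = out
    return q


def inverse_normal_transform(values: np.ndarray, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse normal transform with Blom offsets.

    Maps value with (average) rank r among n non-missing observations to
    Phi^-1((r - offset) / (n - 2*offset + 1)).  Missing values stay missing.
    """
    x = np.asarray(values, dtype=float)
    out = np.full(x.shape, np.nan)
    ok = ~np.isnan(x)
    n = int(ok.sum())
    if n == 0:
        return out
    ranks = sps.rankdata(x[ok], method="average")
    out[ok] = sps.norm.ppf((ranks - offset) / (n - 2.0 * offset + 1.0))
    return out


def auc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the Mann-Whitney rank statistic (ties get half credit)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = sps.rankdata(scores, method="average")
    rank_sum = ranks[labels == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def delong_test(scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    """DeLong two-sided test for two correlated AUCs on the same labels.

    Returns (auc_a, auc_b, p_value).  Identical score vectors give p = 1.0
    by convention (the variance of the difference degenerates to 0).
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels).astype(int)
    if np.array_equal(scores_a, scores_b):
        a = auc_rank(scores_a, labels)
        return a, a, 1.0
    pos = labels == 1
    neg = labels == 0
    m, n = int(pos.sum()), int(neg.sum())
    if m == 0 or n == 0:
        raise ValueError("DeLong test requires both classes present")

    aucs = np.empty(2)
    v01 = np.empty((2, m))
    v10 = np.empty((2, n))
    for k, sc in enumerate((scores_a, scores_b)):
        tx = _midrank(sc[pos])
        ty = _midrank(sc[neg])
        tz = _midrank(sc)
        aucs[k] = (tz[pos].sum() - m * (m + 1) / 2.0) / (m * n)
        v01[k] = (tz[pos] - tx) / n
        v10[k] = 1.0 - (tz[neg] - ty) / m
    s01 = np.cov(v01)
    s10 = np.cov(v10)
    cov = s01 / m + s10 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0:
        return float(aucs[0]), float(aucs[1]), 1.0
    z = (aucs[0] - aucs[1]) / np.sqrt(var_diff)
    p = float(2.0 * sps.norm.sf(abs(z)))
    return float(aucs[0]), float(aucs[1]), min(p, 1.0)


def ward_silhouette_k(matrix: np.ndarray, k_range: range | list[int]) -> tuple[np.ndarray, dict[int, float], int]:
    """Agglomerative Ward/Euclidean clustering with silhouette-chosen k.

    Returns (labels for the chosen k, {k: mean silhouette}, chosen k).
    Ties in silhouette resolve to the smallest k.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if n < 3:
        raise ValueError("need at least 3 observations to cluster")
    scores: dict[int, float] = {}
    labelings: dict[int, np.ndarray] = {}
    for k in k_range:
        if k < 2 or k > n - 1:
            continue
        model = AgglomerativeClustering(n_clusters=k, linkage="ward")
        labels = model.fit_predict(matrix)
        if len(np.unique(labels)) < 2:
            continue
        scores[k] = float(silhouette_score(matrix, labels, metric="euclidean"))
        labelings[k] = labels
    if not scores:
        raise ValueError("no valid k in range")
    best_k = min(scores, key=lambda k: (-scores[k], k))
    return labelings[best_k] + 1, scores, best_k
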