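"""Metabolic risk score: gain-ranked panel selection, calibrated boosted
trees, geography-blocked cross-validation, bootstrap evaluation and exact
tree-path attribution.

The boosted classifier is scikit-learn's histogram gradient boosting
(LightGBM-style leafwise histogram trees); per-feature importance is the
total split gain accumulated over all trees, read from the fitted
predictor node arrays, and per-prediction attributions are computed by
telescoping node values along each decision path (exactly additive to the
raw margin).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.isotonic import IsotonicRegression
from sklearn.model_selection import train_test_split

from ._stats import auc_rank, delong_test

logger = logging.getLogger(__name__)

__all__ = [
    "MetRSModel",
    "FoldModel",
    "EvaluationReport",
    "assign_geographic_folds",
    "rank_and_select",
    "select_panel_across_folds",
    "train_calibrated",
    "evaluate",
    "attribute",
    "cross_validated_metrs",
]

DEMOGRAPHIC_COLUMNS = ["age", "sex", "ethnicity", "tdi", "bmi", "smoking"]

DEFAULT_GRID = (
    {"learning_rate": 0.1, "max_iter": 100, "max_leaf_nodes": 31},
    {"learning_rate": 0.05, "max_iter": 150, "max_leaf_nodes": 15},
)


@dataclass
class FoldModel:
    classifier: HistGradientBoostingClassifier
    calibrator: IsotonicRegression
    feature_names: list
    hyperparameters: dict
    inner_auc: float

    def predict_risk(self, X: pd.DataFrame) -> np.ndarray:
        raw = self.classifier.predict_proba(X[self.feature_names].to_numpy(float))[:, 1]
        return np.clip(self.calibrator.predict(raw), 0.0, 1.0)


@dataclass
class MetRSModel:
    disease_id: str
    task: str  # prevalent | incident
    selected_metabolites: list
    mean_ranks: dict
    fold_models: dict  # fold id -> FoldModel
    fold_assignments: pd.Series
    with_demographics: bool
    seed: int
    oof_scores: Optional[pd.Series] = None


@dataclass
class EvaluationReport:
    auc: float
    ci95: tuple
    n_bootstrap: int
    comparisons: dict = field(default_factory=dict)  # name -> (auc_other, delong_p)
    attributions: Optional[pd.DataFrame] = None


# -- geographic folds -------------------------------------------------------


def assign_geographic_folds(
    assessment_centres: pd.Series, k: int = 10, seed: int = 0
) -> pd.Series:
    """Partition centres (not individuals) into k folds, greedy largest-first.

    Centres sorted by size descending are assigned one by one to the
    currently smallest fold, so all members of a centre always share a
    fold.  Ties break deterministically (fold index, then centre name).
    """
    if assessment_centres.isna().any():
        raise ValueError("every participant needs an assessment centre")
    sizes = assessment_centres.value_counts()
    if len(sizes) < k:
        raise ValueError(f"only {len(sizes)} centres for k={k} folds")
    order = sorted(sizes.index, key=lambda c: (-sizes[c], str(c)))
    fold_total = np.zeros(k, dtype=int)
    centre_fold: dict = {}
    for centre in order:
        f = int(np.argmin(fold_total))
        centre_fold[centre] = f
        fold_total[f] += sizes[centre]
    return assessment_centres.map(centre_fold).astype(int)


# -- boosted trees: fit, gain importance, attribution ----------------------


def _fit_booster(
    X: np.ndarray, y: np.ndarray, seed: int, **params
) -> HistGradientBoostingClassifier:
    clf = HistGradientBoostingClassifier(
        random_state=seed, early_stopping=False, **params
    )
    clf.fit(X, y)
    return clf


def _tree_nodes(clf: HistGradientBoostingClassifier):
    for stage in clf._predictors:
        for predictor in stage:
            yield predictor.nodes


def gain_importances(clf: HistGradientBoostingClassifier, n_features: int) -> np.ndarray:
    """Total split information gain per feature, summed over all trees."""
    imp = np.zeros(n_features)
    for nodes in _tree_nodes(clf):
        internal = nodes[nodes["is_leaf"] == 0]
        np.add.at(imp, internal["feature_idx"].astype(int), internal["gain"])
    return imp


def rank_and_select(
    X: pd.DataFrame,
    y: np.ndarray,
    top_k: int = 30,
    seed: int = 0,
    **booster_params,
) -> tuple[list, list, np.ndarray]:
    """Fit a naive booster on all features and rank them by total gain.

    Returns (features ranked by descending importance, top_k panel,
    importance array).  Deterministic given the seed; ties break by
    column order.
    """
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    params = {"learning_rate": 0.1, "max_iter": 100, "max_leaf_nodes": 31}
    params.update(booster_params)
    clf = _fit_booster(X.to_numpy(float), y, seed, **params)
    imp = gain_importances(clf, X.shape[1])
    order = np.argsort(-imp, kind="mergesort")
    ranked = [X.columns[i] for i in order]
    return ranked, ranked[:top_k], imp


def select_panel_across_folds(fold_rankings: list[list], top_k: int = 30) -> tuple[list, dict]:
    """Final panel: average each feature's rank across folds, take top_k."""
    mean_ranks: dict = {}
    for ranking in fold_rankings:
        for pos, feat in enumerate(ranking, start=1):
            mean_ranks.setdefault(feat, []).append(pos)
    averaged = {f: float(np.mean(r)) for f, r in mean_ranks.items()}
    panel = sorted(averaged, key=lambda f: (averaged[f], str(f)))[:top_k]
    return panel, averaged


def _encode_features(
    z_metabolites: pd.DataFrame,
    panel: list,
    demographics: Optional[pd.DataFrame],
) -> pd.DataFrame:
    missing = [m for m in panel if m not in z_metabolites.columns]
    if missing:
        raise ValueError(f"panel references unknown metabolites: {missing}")
    X = z_metabolites[panel].copy()
    if demographics is not None:
        cols = [c for c in DEMOGRAPHIC_COLUMNS if c in demographics.columns]
        demo = pd.get_dummies(demographics[cols], drop_first=True, dtype=float)
        X = pd.concat([X, demo.loc[X.index]], axis=1)
    return X.astype(float)


def train_calibrated(
    z_metabolites: pd.DataFrame,
    y: pd.Series,
    panel: list,
    demographics: Optional[pd.DataFrame] = None,
    seed: int = 0,
    grid: tuple = DEFAULT_GRID,
    inner_fraction: float = 0.2,
) -> FoldModel:
    """Tune on an inner 80/20 split, then calibrate isotonic on the inner
    out-of-sample predictions (never the boosting rows)."""
    X = _encode_features(z_metabolites, panel, demographics)
    yv = np.asarray(y.loc[X.index]).astype(int)
    if len(np.unique(yv)) < 2:
        raise ValueError("training labels contain a single class")
    Xtr, Xval, ytr, yval = train_test_split(
        X.to_numpy(float), yv, test_size=inner_fraction, random_state=seed, stratify=yv
    )
    best = None
    for params in grid:
        clf = _fit_booster(Xtr, ytr, seed, **params)
        val_scores = clf.predict_proba(Xval)[:, 1]
        auc = auc_rank(val_scores, yval)
        if best is None or auc > best[0]:
            best = (auc, params, clf, val_scores)
    inner_auc, params, clf, val_scores = best
    calibrator = IsotonicRegression(out_of_bounds="clip", y_min=0.0, y_max=1.0)
    calibrator.fit(val_scores, yval)
    return FoldModel(
        classifier=clf,
        calibrator=calibrator,
        feature_names=list(X.columns),
        hyperparameters=dict(params),
        inner_auc=float(inner_auc),
    )


def cross_validated_metrs(
    z_metabolites: pd.DataFrame,
    labels: pd.Series,
    assessment_centres: pd.Series,
    demographics: Optional[pd.DataFrame] = None,
    disease_id: str = "",
    task: str = "incident",
    k: int = 10,
    top_k: int = 30,
    seed: int = 0,
    ranking_params: Optional[dict] = None,
    grid: tuple = DEFAULT_GRID,
) -> MetRSModel:
    """Geography-blocked k-fold CV: per-fold ranking, tuning, calibration.

    Ranking, hyperparameter tuning and calibration only ever see the nine
    training folds; the held-out fold contributes out-of-fold scores.
    """
    folds = assign_geographic_folds(assessment_centres, k=k, seed=seed)
    ids = z_metabolites.index
    y = labels.loc[ids].astype(int)
    fold_rankings = []
    fold_models: dict = {}
    oof = pd.Series(np.nan, index=ids, dtype=float)
    for f in range(k):
        train_ids = ids[folds.loc[ids] != f]
        test_ids = ids[folds.loc[ids] == f]
        if len(test_ids) == 0 or y.loc[train_ids].nunique() < 2:
            logger.warning("fold %d skipped (empty or single-class)", f)
            continue
        ranked, _, _ = rank_and_select(
            z_metabolites.loc[train_ids], y.loc[train_ids], top_k=top_k,
            seed=seed + f, **(ranking_params or {}),
        )
        fold_rankings.append(ranked)
        panel_f = ranked[:top_k]
        fm = train_calibrated(
            z_metabolites.loc[train_ids],
            y.loc[train_ids],
            panel_f,
            demographics=None if demographics is None else demographics.loc[train_ids],
            seed=seed + f,
            grid=grid,
        )
        fold_models[f] = fm
        Xte = _encode_features(
            z_metabolites.loc[test_ids],
            panel_f,
            None if demographics is None else demographics.loc[test_ids],
        )
        oof.loc[test_ids] = fm.predict_risk(Xte)
    panel, mean_ranks = select_panel_across_folds(fold_rankings, top_k=top_k)
    return MetRSModel(
        disease_id=disease_id,
        task=task,
        selected_metabolites=panel,
        mean_ranks=mean_ranks,
        fold_models=fold_models,
        fold_assignments=folds,
        with_demographics=demographics is not None,
        seed=seed,
        oof_scores=oof,
    )


# -- evaluation -------------------------------------------------------------


def evaluate(
    scores: np.ndarray,
    labels: np.ndarray,
    n_bootstrap: int = 1000,
    seed: int = 0,
    comparisons: Optional[dict] = None,
) -> EvaluationReport:
    """AUC with percentile bootstrap CI; optional DeLong comparisons.

    ``comparisons`` maps a name to another score vector on the same labels.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels contain a single class")
    auc = auc_rank(scores, labels)
    rng = np.random.default_rng(seed)
    n = len(labels)
    boot = []
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        yb = labels[idx]
        if yb.min() == yb.max():
            continue
        boot.append(auc_rank(scores[idx], yb))
    lo, hi = np.percentile(boot, [2.5, 97.5])
    comp_results = {}
    for name, other in (comparisons or {}).items():
        a, b, p = delong_test(scores, np.asarray(other, dtype=float), labels)
        comp_results[name] = {"auc_self": a, "auc_other": b, "delong_p": p}
    return EvaluationReport(
        auc=float(auc), ci95=(float(lo), float(hi)), n_bootstrap=n_bootstrap,
        comparisons=comp_results,
    )


# -- attribution ------------------------------------------------------------


def attribute(
    model: FoldModel | HistGradientBoostingClassifier, X: pd.DataFrame
) -> tuple[np.ndarray, float, bool]:
    """Per-prediction additive feature contributions on the raw margin scale.

    Walks each sample's decision path in every tree and attributes the
    change in node value to the split feature of the parent node; the
    contributions plus the base value reproduce the model's raw margin
    exactly.  Returns (contributions n x p, base_value, exact_flag).
    """
    if isinstance(model, FoldModel):
        clf = model.classifier
        Xn = X[model.feature_names].to_numpy(float)
    else:
        clf = model
        Xn = X.to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    if not hasattr(clf, "_predictors"):
        logger.warning("non-tree model: falling back to permutation attribution")
        return _permutation_attribution(clf, Xn)
    n, p = Xn.shape
    contrib = np.zeros((n, p))
    base = float(np.ravel(clf._baseline_prediction)[0])
    for nodes in _tree_nodes(clf):
        base += float(nodes[0]["value"])
        for i in range(n):
            node = 0
            while not nodes[node]["is_leaf"]:
                feat = int(nodes[node]["feature_idx"])
                xval = Xn[i, feat]
                if np.isnan(xval):
                    child = nodes[node]["left"] if nodes[node]["missing_go_to_left"] else nodes[node]["right"]
                elif xval <= nodes[node]["num_threshold"]:
                    child = nodes[node]["left"]
                else:
                    child = nodes[node]["right"]
                contrib[i, feat] += float(nodes[child]["value"]) - float(nodes[node]["value"])
                node = int(child)
    return contrib, base, True


def _permutation_attribution(clf, Xn: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """Global (not per-path-exact) fallback: score drop under permutation."""
    rng = np.random.default_rng(0)
    baseline = clf.predict_proba(Xn)[:, 1]
    n, p = Xn.shape
    contrib = np.zeros((n, p))
    for j in range(p):
        Xp = Xn.copy()
        Xp[:, j] = rng.permutation(Xp[:, j])
        contrib[:, j] = baseline - clf.predict_proba(Xp)[:, 1]
    return contrib, float(np.mean(baseline)), False


def normalized_mean_attribution(contrib: np.ndarray, feature_names: list) -> pd.DataFrame:
    """Mean |contribution| per feature, normalized to sum to 1, with sign."""
    mean_abs = np.abs(contrib).mean(axis=0)
    total = mean_abs.sum() or 1.0
    direction = np.sign(np.nanmean(np.where(contrib == 0, np.nan, contrib), axis=0))
    return pd.DataFrame(
        {
            "feature": feature_names,
            "mean_abs_contribution": mean_abs / total,
            "direction": np.nan_to_num(direction),
        }
    ).sort_values("mean_abs_contribution", ascending=False, ignore_index=True)
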