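"""Phenome-wide association scans with multiplicity control and replication.

One metabolite at a time (marginal scans), adjusted for a fixed covariate
set.  Model choice follows the phenotype family:

* prevalent disease  -> logistic regression (case/control)
* incident disease   -> Cox proportional hazards (Efron ties), time-on-study
* continuous trait   -> OLS on the inverse-normal-transformed trait
* binary trait       -> OLS with the metabolite as outcome and the trait as
                        predictor (reversed orientation)
* ordinal trait      -> proportional-odds logistic regression

Failed fits are reported with a diagnostic, never silently dropped, so the
multiplicity denominator stays explicit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from statsmodels.miscmodels.ordinal_model import OrderedModel

from ._stats import bh_adjust, inverse_normal_transform

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisSet",
    "AssociationRecord",
    "bonferroni_threshold",
    "build_analysis_sets",
    "scan_associations",
    "subgroup_and_interaction",
    "replicate_fdr",
    "records_to_frame",
]

DEFAULT_COVARIATES = ["age", "sex", "tdi", "bmi", "smoking", "statin", "fasting_time"]
_TINY_P = float(np.nextafter(0.0, 1.0))


def bonferroni_threshold(alpha: float, n_metabolites: int, n_phenotypes: int) -> float:
    """Family-wise error threshold alpha / (n_metabolites * n_phenotypes)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    if n_metabolites < 1 or n_phenotypes < 1:
        raise ValueError("counts must be >= 1")
    return alpha / (n_metabolites * n_phenotypes)


@dataclass
class AnalysisSet:
    phenotype_id: str
    kind: str  # prevalent | incident | trait_continuous | trait_binary | trait_ordinal
    case_ids: list = field(default_factory=list)
    control_ids: list = field(default_factory=list)
    eligible_ids: list = field(default_factory=list)  # traits: all usable rows
    trait_values: Optional[pd.Series] = None  # traits: raw values, index = id
    durations: Optional[pd.Series] = None  # incident only: min(onset, censor)
    events: Optional[pd.Series] = None  # incident only: 1 if onset observed
    exclusions: dict = field(default_factory=dict)  # participant id -> reason
    included: bool = True
    reason: Optional[str] = None

    @property
    def n_cases(self) -> int:
        return len(self.case_ids)


@dataclass
class AssociationRecord:
    metabolite_id: str
    phenotype_id: str
    model_kind: str  # logistic | cox | linear | ordinal_logistic
    effect: float = np.nan  # log-OR / log-HR / beta per SD of metabolite
    se: float = np.nan
    ci95: tuple = (np.nan, np.nan)
    p_value: float = np.nan
    n: int = 0
    n_cases: int = 0
    stratum: str = "all"
    orientation: str = "phenotype~metabolite"
    passes_bonferroni: bool = False
    replication_p: Optional[float] = None
    passes_fdr: Optional[bool] = None
    failed: bool = False
    diagnostic: Optional[str] = None


def build_analysis_sets(
    registry: pd.DataFrame,
    traits: Optional[pd.DataFrame] = None,
    trait_kinds: Optional[dict] = None,
    min_cases: int = 300,
    trait_min_n: int = 10_000,
    binary_min_cell: int = 50,
) -> list[AnalysisSet]:
    """Build eligible case/control sets per phenotype with explicit exclusions.

    Controls for a disease are participants who never develop it.  The
    incident analysis excludes prevalent cases of the same disease and the
    prevalent analysis excludes incident cases; both exclusions are logged
    per participant.  Undersized phenotypes stay in the list with
    ``included=False`` and a reason.
    """
    sets: list[AnalysisSet] = []
    if registry is not None and len(registry):
        for disease_id, sub in registry.groupby("disease_id", sort=True):
            sub = sub.set_index("participant_id")
            prevalent = sub.index[sub["status"] == "prevalent"]
            incident = sub.index[sub["status"] == "incident"]
            never = sub.index[sub["status"] == "never"]

            inc_set = AnalysisSet(
                phenotype_id=str(disease_id),
                kind="incident",
                case_ids=list(incident),
                control_ids=list(never),
                exclusions={str(i): "prevalent diagnosis" for i in prevalent},
            )
            dur = sub["onset_time"].where(sub["status"] == "incident", sub["censor_time"])
            keep = inc_set.case_ids + inc_set.control_ids
            inc_set.durations = dur.loc[keep]
            inc_set.events = pd.Series(
                np.where(sub.loc[keep, "status"] == "incident", 1, 0), index=keep
            )
            if len(incident) < min_cases:
                inc_set.included = False
                inc_set.reason = f"<{min_cases} cases"
            sets.append(inc_set)

            prev_set = AnalysisSet(
                phenotype_id=str(disease_id),
                kind="prevalent",
                case_ids=list(prevalent),
                control_ids=list(never),
                exclusions={str(i): "incident during follow-up" for i in incident},
            )
            if len(prevalent) < min_cases:
                prev_set.included = False
                prev_set.reason = f"<{min_cases} cases"
            sets.append(prev_set)

    if traits is not None:
        trait_kinds = trait_kinds or {}
        for trait_id in traits.columns:
            kind = trait_kinds.get(trait_id, "continuous")
            if kind not in ("continuous", "ordinal", "binary"):
                raise ValueError(f"unknown trait kind {kind!r} for {trait_id!r}")
            values = traits[trait_id]
            eligible = list(values.dropna().index)
            tset = AnalysisSet(
                phenotype_id=str(trait_id),
                kind=f"trait_{kind}",
                eligible_ids=eligible,
                trait_values=values.dropna(),
            )
            if len(eligible) < trait_min_n:
                tset.included = False
                tset.reason = f"n<{trait_min_n}"
            elif kind == "binary":
                vals = values.dropna()
                cases = list(vals.index[vals == 1])
                controls = list(vals.index[vals == 0])
                tset.case_ids, tset.control_ids = cases, controls
                if min(len(cases), len(controls)) < binary_min_cell:
                    tset.included = False
                    tset.reason = f"<{binary_min_cell} cases or controls"
            sets.append(tset)
    return sets


# -- covariate design -------------------------------------------------------


def build_design(
    covariates: pd.DataFrame,
    covariate_names: list[str] | None = None,
    drop: tuple = (),
) -> pd.DataFrame:
    """Numeric design matrix (dummy-coded, drop-first) without intercept."""
    names = [c for c in (covariate_names or DEFAULT_COVARIATES) if c not in drop]
    names = [c for c in names if c in covariates.columns]
    X = pd.get_dummies(covariates[names], drop_first=True, dtype=float)
    return X.astype(float)


def _clip_p(p: float) -> float:
    return float(min(max(p, _TINY_P), 1.0))


def _record_from_fit(
    rec: AssociationRecord, effect: float, se: float, p: float, link_exp: bool
) -> AssociationRecord:
    rec.effect = float(effect)
    rec.se = float(se)
    rec.p_value = _clip_p(p)
    lo, hi = effect - 1.96 * se, effect + 1.96 * se
    rec.ci95 = (float(np.exp(lo)), float(np.exp(hi))) if link_exp else (float(lo), float(hi))
    return rec


def _fit_logistic(y: np.ndarray, X: pd.DataFrame, term: str):
    Xc = sm.add_constant(X, has_constant="add")
    model = sm.Logit(y, Xc.astype(float))
    res = model.fit(disp=0, maxiter=200)
    if not res.mle_retvals.get("converged", True):
        raise RuntimeError("logistic fit did not converge")
    return res.params[term], res.bse[term], res.pvalues[term]


def _fit_ols(y: np.ndarray, X: pd.DataFrame, term: str):
    Xc = sm.add_constant(X, has_constant="add")
    res = sm.OLS(y, Xc.astype(float)).fit()
    return res.params[term], res.bse[term], res.pvalues[term]


def _fit_cox(frame: pd.DataFrame, term: str):
    cph = CoxPHFitter()
    cph.fit(frame, duration_col="_duration", event_col="_event")
    return (
        cph.params_[term],
        cph.standard_errors_[term],
        cph.summary.loc[term, "p"],
    )


def _fit_ordinal(y: pd.Series, X: pd.DataFrame, term: str):
    model = OrderedModel(y.astype(int), X.astype(float), distr="logit")
    res = model.fit(method="bfgs", disp=0, maxiter=200)
    if not res.mle_retvals.get("converged", True):
        raise RuntimeError("ordinal fit did not converge")
    return res.params[term], res.bse[term], res.pvalues[term]


def scan_associations(
    z_metabolites: pd.DataFrame,
    analysis_sets: list[AnalysisSet],
    covariates: pd.DataFrame,
    covariate_names: list[str] | None = None,
    alpha: float = 0.05,
    stratum: str = "all",
    drop_covariates: tuple = (),
    bonferroni_n_phenotypes: Optional[int] = None,
) -> list[AssociationRecord]:
    """One AssociationRecord per metabolite x included phenotype.

    ``passes_bonferroni`` is evaluated against alpha / (m * P) where m is
    the number of metabolite columns and P the number of included
    phenotypes in this call (overridable via ``bonferroni_n_phenotypes``).
    """
    included = [s for s in analysis_sets if s.included]
    if not included:
        return []
    n_phen = bonferroni_n_phenotypes or len(included)
    threshold = bonferroni_threshold(alpha, z_metabolites.shape[1], n_phen)

    records: list[AssociationRecord] = []
    base_design = build_design(covariates, covariate_names, drop=drop_covariates)
    for aset in included:
        records.extend(
            _scan_one_phenotype(z_metabolites, aset, base_design, stratum, threshold)
        )
    return records


def _scan_one_phenotype(
    z_metabolites: pd.DataFrame,
    aset: AnalysisSet,
    base_design: pd.DataFrame,
    stratum: str,
    threshold: float,
) -> list[AssociationRecord]:
    records = []
    if aset.kind in ("prevalent", "incident"):
        ids = [i for i in aset.case_ids + aset.control_ids if i in z_metabolites.index]
    else:
        ids = [i for i in aset.eligible_ids if i in z_metabolites.index]
    X0 = base_design.loc[ids]
    for met in z_metabolites.columns:
        rec = AssociationRecord(
            metabolite_id=met, phenotype_id=aset.phenotype_id, model_kind="linear",
            stratum=stratum,
        )
        mvals = z_metabolites.loc[ids, met]
        ok = ~mvals.isna()
        use = list(mvals.index[ok])
        X = X0.loc[use].copy()
        X[met] = mvals.loc[use]
        rec.n = len(use)
        try:
            if aset.kind == "prevalent":
                rec.model_kind = "logistic"
                case_set = set(aset.case_ids)
                y = np.array([1 if i in case_set else 0 for i in use])
                rec.n_cases = int(y.sum())
                eff, se, p = _fit_logistic(y, X, met)
                _record_from_fit(rec, eff, se, p, link_exp=True)
            elif aset.kind == "incident":
                rec.model_kind = "cox"
                frame = X.copy()
                frame["_duration"] = aset.durations.loc[use]
                frame["_event"] = aset.events.loc[use]
                rec.n_cases = int(frame["_event"].sum())
                eff, se, p = _fit_cox(frame, met)
                _record_from_fit(rec, eff, se, p, link_exp=True)
            elif aset.kind == "trait_continuous":
                rec.model_kind = "linear"
                y = inverse_normal_transform(aset.trait_values.loc[use].to_numpy())
                eff, se, p = _fit_ols(y, X, met)
                _record_from_fit(rec, eff, se, p, link_exp=False)
            elif aset.kind == "trait_binary":
                rec.model_kind = "linear"
                rec.orientation = "metabolite~trait"
                case_set = set(aset.case_ids)
                t = np.array([1.0 if i in case_set else 0.0 for i in use])
                rec.n_cases = int(t.sum())
                Xb = X.drop(columns=[met]).copy()
                Xb["_trait"] = t
                eff, se, p = _fit_ols(mvals.loc[use].to_numpy(), Xb, "_trait")
                _record_from_fit(rec, eff, se, p, link_exp=False)
            elif aset.kind == "trait_ordinal":
                rec.model_kind = "ordinal_logistic"
                eff, se, p = _fit_ordinal(aset.trait_values.loc[use], X, met)
                _record_from_fit(rec, eff, se, p, link_exp=False)
            else:  # pragma: no cover
                raise ValueError(f"unknown analysis-set kind {aset.kind!r}")
            rec.passes_bonferroni = bool(rec.p_value < threshold)
        except Exception as exc:  # noqa: BLE001 - scans must continue
            rec.failed = True
            rec.diagnostic = f"{type(exc).__name__}: {exc}"
            logger.warning("fit failed for %s x %s: %s", met, aset.phenotype_id, exc)
        records.append(rec)
    return records


def subgroup_and_interaction(
    z_metabolites: pd.DataFrame,
    analysis_sets: list[AnalysisSet],
    covariates: pd.DataFrame,
    covariate_names: list[str] | None = None,
    age_cut: float = 60.0,
    alpha: float = 0.05,
    min_cases: int = 300,
) -> tuple[list[AssociationRecord], list[dict], list[dict]]:
    """Sex / age subgroup scans, interaction terms, and divergence flags.

    Sex-stratified scans drop the sex covariate; age-stratified scans keep
    the full covariate set.  A metabolite-phenotype pair is flagged
    "divergent" when it passes Bonferroni in both strata of a pair with
    opposite effect signs.
    """
    strata = {
        "female": (covariates["sex"] == "female", ("sex",)),
        "male": (covariates["sex"] == "male", ("sex",)),
        "age<60": (covariates["age"] < age_cut, ()),
        "age>=60": (covariates["age"] >= age_cut, ()),
    }
    all_records: list[AssociationRecord] = []
    for label, (mask, drop) in strata.items():
        keep = set(covariates.index[mask])
        sub_sets = []
        for aset in analysis_sets:
            if not aset.included:
                continue
            s = _restrict_set(aset, keep)
            if s.kind in ("prevalent", "incident") and s.n_cases < min_cases:
                logger.info("stratum %s: %s skipped (<%d cases)", label, s.phenotype_id, min_cases)
                continue
            sub_sets.append(s)
        recs = scan_associations(
            z_metabolites.loc[z_metabolites.index.isin(keep)],
            sub_sets,
            covariates.loc[covariates.index.isin(keep)],
            covariate_names,
            alpha=alpha,
            stratum=label,
            drop_covariates=drop,
        )
        all_records.extend(recs)

    divergent = _divergence_flags(all_records, [("female", "male"), ("age<60", "age>=60")])
    interactions = _interaction_terms(
        z_metabolites, analysis_sets, covariates, covariate_names, age_cut
    )
    return all_records, divergent, interactions


def _restrict_set(aset: AnalysisSet, keep: set) -> AnalysisSet:
    s = AnalysisSet(
        phenotype_id=aset.phenotype_id,
        kind=aset.kind,
        case_ids=[i for i in aset.case_ids if i in keep],
        control_ids=[i for i in aset.control_ids if i in keep],
        eligible_ids=[i for i in aset.eligible_ids if i in keep],
        trait_values=None
        if aset.trait_values is None
        else aset.trait_values.loc[[i for i in aset.eligible_ids if i in keep]],
    )
    if aset.durations is not None:
        ids = s.case_ids + s.control_ids
        s.durations = aset.durations.loc[ids]
        s.events = aset.events.loc[ids]
    return s


def _divergence_flags(records: list[AssociationRecord], pairs: list[tuple]) -> list[dict]:
    by_key: dict = {}
    for r in records:
        by_key[(r.metabolite_id, r.phenotype_id, r.stratum)] = r
    flags = []
    for a_label, b_label in pairs:
        keys = {(m, p) for (m, p, s) in by_key if s == a_label}
        for met, phen in sorted(keys):
            ra = by_key.get((met, phen, a_label))
            rb = by_key.get((met, phen, b_label))
            if ra is None or rb is None or ra.failed or rb.failed:
                continue
            if (
                ra.passes_bonferroni
                and rb.passes_bonferroni
                and np.sign(ra.effect) != np.sign(rb.effect)
            ):
                flags.append(
                    {
                        "metabolite_id": met,
                        "phenotype_id": phen,
                        "strata": (a_label, b_label),
                        "effects": (ra.effect, rb.effect),
                    }
                )
    return flags


def _interaction_terms(
    z_metabolites: pd.DataFrame,
    analysis_sets: list[AnalysisSet],
    covariates: pd.DataFrame,
    covariate_names: list[str] | None,
    age_cut: float,
) -> list[dict]:
    """Metabolite x sex and metabolite x age-group interaction P values."""
    results = []
    base = build_design(covariates, covariate_names)
    modifiers = {
        "sex": (covariates["sex"] == "male").astype(float),
        "age_group": (covariates["age"] >= age_cut).astype(float),
    }
    for aset in analysis_sets:
        if not aset.included or aset.kind not in ("prevalent", "incident"):
            continue
        ids = [i for i in aset.case_ids + aset.control_ids if i in z_metabolites.index]
        case_set = set(aset.case_ids)
        for met in z_metabolites.columns:
            for mod_name, mod in modifiers.items():
                X = base.loc[ids].copy()
                X[met] = z_metabolites.loc[ids, met]
                X["_ix"] = X[met] * mod.loc[ids]
                try:
                    if aset.kind == "prevalent":
                        y = np.array([1 if i in case_set else 0 for i in ids])
                        _, _, p = _fit_logistic(y, X, "_ix")
                    else:
                        frame = X.copy()
                        frame["_duration"] = aset.durations.loc[ids]
                        frame["_event"] = aset.events.loc[ids]
                        _, _, p = _fit_cox(frame, "_ix")
                    results.append(
                        {
                            "metabolite_id": met,
                            "phenotype_id": aset.phenotype_id,
                            "modifier": mod_name,
                            "p_value": _clip_p(p),
                        }
                    )
                except Exception as exc:  # noqa: BLE001
                    results.append(
                        {
                            "metabolite_id": met,
                            "phenotype_id": aset.phenotype_id,
                            "modifier": mod_name,
                            "p_value": np.nan,
                            "diagnostic": str(exc),
                        }
                    )
    return results


def replicate_fdr(
    derivation_records: list[AssociationRecord],
    z_metabolites_rep: pd.DataFrame,
    analysis_sets_rep: list[AnalysisSet],
    covariates_rep: pd.DataFrame,
    covariate_names: list[str] | None = None,
    fdr_level: float = 0.05,
) -> list[AssociationRecord]:
    """Re-fit Bonferroni-significant pairs in a replication cohort, BH at 0.05.

    Pairs that cannot be tested in replication are marked "unavailable" and
    excluded from the BH family.
    """
    sets_by_id = {(s.phenotype_id, s.kind): s for s in analysis_sets_rep if s.included}
    base = build_design(covariates_rep, covariate_names)
    threshold = 0.0  # bonferroni flag irrelevant in replication refits
    significant = [r for r in derivation_records if r.passes_bonferroni and not r.failed]
    out: list[AssociationRecord] = []
    for r in significant:
        kind = {"logistic": "prevalent", "cox": "incident"}.get(r.model_kind)
        if kind is None:
            kind = {
                "linear": "trait_continuous" if r.orientation == "phenotype~metabolite" else "trait_binary",
                "ordinal_logistic": "trait_ordinal",
            }[r.model_kind]
        aset = sets_by_id.get((r.phenotype_id, kind))
        rec = AssociationRecord(
            metabolite_id=r.metabolite_id, phenotype_id=r.phenotype_id, model_kind=r.model_kind
        )
        if aset is None:
            rec.failed = True
            rec.diagnostic = "unavailable"
        else:
            fitted = _scan_one_phenotype(
                z_metabolites_rep[[r.metabolite_id]], aset, base, "replication", threshold
            )[0]
            rec = fitted
        out.append(rec)

    testable = [r for r in out if not r.failed]
    qs = bh_adjust(np.array([r.p_value for r in testable]))
    for r, q in zip(testable, qs):
        r.passes_fdr = bool(q < fdr_level)
    for orig, rep in zip(significant, out):
        orig.replication_p = None if rep.failed else rep.p_value
        orig.passes_fdr = None if rep.failed else rep.passes_fdr
    return out


def records_to_frame(records: list[AssociationRecord]) -> pd.DataFrame:
    """Long-format table, one row per record (associations.tsv layout)."""
    rows = []
    for r in records:
        rows.append(
            {
                "metabolite_id": r.metabolite_id,
                "phenotype_id": r.phenotype_id,
                "model_kind": r.model_kind,
                "stratum": r.stratum,
                "orientation": r.orientation,
                "effect": r.effect,
                "se": r.se,
                "ci95_low": r.ci95[0],
                "ci95_high": r.ci95[1],
                "p_value": r.p_value,
                "n": r.n,
                "n_cases": r.n_cases,
                "passes_bonferroni": r.passes_bonferroni,
                "replication_p": r.replication_p,
                "passes_fdr": r.passes_fdr,
                "failed": r.failed,
                "diagnostic": r.diagnostic,
            }
        )
    return pd.DataFrame(rows)
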