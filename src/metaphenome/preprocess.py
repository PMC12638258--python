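"""Metabolite QC/transform chain, covariate imputation and correlations.

The QC chain is: flag raw values outside median +/- 4*IQR as missing
(quantiles by linear interpolation, numpy's default, configurable), then
natural-log transform and z-standardize the retained values.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "DegenerateInputError",
    "TransformReport",
    "qc_transform",
    "impute_covariates",
    "correlation_matrix",
]


class DegenerateInputError(ValueError):
    """Raised when a metabolite cannot be transformed (zero variance, <=0 values)."""


@dataclass
class MetaboliteQC:
    median: float
    iqr: float
    lower: float
    upper: float
    n_outliers: int
    outlier_ids: list
    post_mean: float
    post_sd: float


@dataclass
class ImputationRecord:
    column: str
    kind: str  # "mode" or "median"
    n_filled: int
    fills: dict  # stratum -> fill value


@dataclass
class TransformReport:
    """Record of every QC / imputation decision, JSON-serializable."""

    metabolites: dict = field(default_factory=dict)  # name -> MetaboliteQC
    covariates: dict = field(default_factory=dict)  # name -> ImputationRecord
    notes: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "metabolites": {k: asdict(v) for k, v in self.metabolites.items()},
                "covariates": {k: asdict(v) for k, v in self.covariates.items()},
                "notes": self.notes,
            },
            indent=2,
        )


def qc_transform(
    raw: pd.DataFrame,
    iqr_multiplier: float = 4.0,
    quantile_method: str = "linear",
    remove_outliers: bool = True,
    min_non_missing: int = 10,
) -> tuple[pd.DataFrame, TransformReport]:
    """Outlier-mask, log-transform and z-standardize a raw metabolite table.

    Outliers are values outside ``median +/- iqr_multiplier * IQR`` computed
    on the raw scale; they are set missing before the log/z steps.
    """
    report = TransformReport()
    out = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        values = raw[col].to_numpy(dtype=float)
        present = ~np.isnan(values)
        if present.sum() < min_non_missing:
            raise DegenerateInputError(
                f"metabolite {col!r}: only {int(present.sum())} non-missing values"
            )
        if remove_outliers:
            q1, q3 = np.quantile(values[present], [0.25, 0.75], method=quantile_method)
            med = float(np.median(values[present]))
            iqr = float(q3 - q1)
            lower = med - iqr_multiplier * iqr
            upper = med + iqr_multiplier * iqr
            outliers = present & ((values < lower) | (values > upper))
        else:
            med = float(np.median(values[present]))
            iqr = float(np.subtract(*np.quantile(values[present], [0.75, 0.25])))
            lower, upper = -np.inf, np.inf
            outliers = np.zeros_like(present)
        keep = present & ~outliers
        kept = values[keep]
        if np.any(kept <= 0):
            raise DegenerateInputError(
                f"metabolite {col!r}: non-positive value encountered for log transform"
            )
        logged = np.log(kept)
        sd = float(logged.std(ddof=0))
        if sd == 0.0:
            raise DegenerateInputError(f"metabolite {col!r}: zero variance after outlier removal")
        mean = float(logged.mean())
        z = np.full(values.shape, np.nan)
        z[keep] = (logged - mean) / sd
        out[col] = z
        report.metabolites[col] = MetaboliteQC(
            median=med,
            iqr=iqr,
            lower=float(lower),
            upper=float(upper),
            n_outliers=int(outliers.sum()),
            outlier_ids=[str(i) for i in raw.index[outliers]],
            post_mean=float(np.nanmean(z)),
            post_sd=float(np.nanstd(z, ddof=0)),
        )
    return out, report


def impute_covariates(
    table: pd.DataFrame,
    sex_column: str = "sex",
    exclude: tuple = ("assessment_centre",),
    warn_threshold: float = 0.05,
) -> tuple[pd.DataFrame, TransformReport]:
    """Fill missing covariates with within-sex mode (discrete) / median (continuous).

    Mode ties break to the lexicographically smallest category.  A stratum
    with no observed values falls back to the overall mode/median (logged).
    Non-missing entries are preserved bit-exactly.
    """
    if table[sex_column].isna().any():
        raise ValueError(f"{sex_column!r} column must be complete before imputation")
    report = TransformReport()
    out = table.copy()
    for col in table.columns:
        if col == sex_column or col in exclude:
            continue
        missing = out[col].isna()
        if not missing.any():
            continue
        frac = missing.mean()
        if frac > warn_threshold:
            msg = f"covariate {col!r}: {frac:.1%} missing exceeds {warn_threshold:.0%}; imputing anyway"
            logger.warning(msg)
            report.notes.append(msg)
        discrete = out[col].dtype == object or str(out[col].dtype) == "category"
        fills: dict = {}
        for stratum, grp in out.groupby(sex_column):
            observed = grp[col].dropna()
            if observed.empty:
                observed = out[col].dropna()
                msg = f"covariate {col!r}: stratum {stratum!r} empty; overall fallback used"
                logger.warning(msg)
                report.notes.append(msg)
            if discrete:
                counts = observed.value_counts()
                top = counts[counts == counts.max()]
                fill = sorted(top.index)[0]
                if len(top) > 1:
                    report.notes.append(
                        f"covariate {col!r}: mode tie in stratum {stratum!r}; chose {fill!r}"
                    )
            else:
                fill = float(observed.median())
            fills[str(stratum)] = fill
            idx = missing & (out[sex_column] == stratum)
            out.loc[idx, col] = fill
        report.covariates[col] = ImputationRecord(
            column=col,
            kind="mode" if discrete else "median",
            n_filled=int(missing.sum()),
            fills=fills,
        )
    return out, report


def correlation_matrix(z_matrix: pd.DataFrame, min_pairs: int = 3) -> pd.DataFrame:
    """Pairwise-complete Spearman correlations; unit diagonal; NaN where degenerate."""
    cols = list(z_matrix.columns)
    data = z_matrix.to_numpy(dtype=float)
    m = len(cols)
    corr = np.eye(m)
    zero_var = []
    for j in range(m):
        col = data[:, j]
        ok = ~np.isnan(col)
        if ok.sum() >= 2 and np.nanstd(col) == 0:
            zero_var.append(j)
    for a in range(m):
        for b in range(a + 1, m):
            both = ~np.isnan(data[:, a]) & ~np.isnan(data[:, b])
            npairs = int(both.sum())
            if npairs < min_pairs or a in zero_var or b in zero_var:
                corr[a, b] = corr[b, a] = np.nan
                continue
            xa, xb = data[both, a], data[both, b]
            if np.std(xa) == 0 or np.std(xb) == 0:
                corr[a, b] = corr[b, a] = np.nan
                logger.warning("zero rank variance in pair (%s, %s)", cols[a], cols[b])
                continue
            rho = sps.spearmanr(xa, xb).statistic
            corr[a, b] = corr[b, a] = rho
    if zero_var:
        logger.warning("columns with zero variance: %s", [cols[j] for j in zero_var])
    return pd.DataFrame(corr, index=cols, columns=cols)
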