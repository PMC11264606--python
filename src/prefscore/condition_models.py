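"""Utility regressions on 22 binary health-condition indicators.

One OLS model per outcome, all 22 indicators entered simultaneously, no
selection or shrinkage.  The per-condition coefficient is the adjusted
mean utility decrement of having the condition; the zero-order correlation
is the unadjusted association, so a coefficient may carry the opposite
sign (a suppression effect).  The two outcomes' 22-element coefficient
vectors are compared by their product-moment correlation.

The packaged ``published_condition_effects`` table holds the source study's
printed general-population estimates (prevalence, coefficient and
zero-order correlation per condition, for both outcomes, at 2-3 decimal
printed precision) and is used both as a reference fixture and as the
default generating truth for the synthetic cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import (
    InsufficientDataError,
    RankDeficiencyError,
    SchemaError,
    ValidationError,
)

#: Canonical 22-condition list, in published table order.
CONDITIONS = (
    "hypertension",
    "high_cholesterol",
    "heart_disease",
    "angina",
    "heart_attack",
    "stroke",
    "asthma",
    "cancer",
    "diabetes",
    "copd",
    "arthritis",
    "anxiety",
    "depression",
    "allergies",
    "back_pain",
    "sciatica",
    "neck_pain",
    "trouble_seeing",
    "dermatitis",
    "stomach_trouble",
    "trouble_hearing",
    "trouble_sleeping",
)

#: Careless-responder screening items; never entered as regressors.
FAKE_CONDITIONS = ("syndomitis", "chekalism")

_PUBLISHED_ROWS = [
    # condition, prevalence, propr_beta, propr_zero_order, eq5d_beta, eq5d_zero_order
    ("hypertension", 0.38, -0.009, -0.16, -0.024, -0.20),
    ("high_cholesterol", 0.38, 0.015, -0.11, 0.001, -0.13),
    ("heart_disease", 0.06, -0.001, -0.07, -0.004, -0.09),
    ("angina", 0.02, -0.022, -0.09, -0.025, -0.10),
    ("heart_attack", 0.03, -0.001, -0.06, -0.001, -0.07),
    ("stroke", 0.03, -0.030, -0.08, -0.058, -0.11),
    ("asthma", 0.13, -0.013, -0.14, -0.009, -0.13),
    ("cancer", 0.10, 0.020, -0.03, 0.009, -0.05),
    ("diabetes", 0.13, -0.057, -0.16, -0.032, -0.17),
    ("copd", 0.05, -0.044, -0.15, -0.069, -0.19),
    ("arthritis", 0.30, -0.031, -0.26, -0.046, -0.32),
    ("anxiety", 0.20, -0.055, -0.35, -0.041, -0.34),
    ("depression", 0.20, -0.112, -0.46, -0.078, -0.38),
    ("allergies", 0.45, 0.012, -0.15, 0.015, -0.14),
    ("back_pain", 0.38, -0.069, -0.37, -0.052, -0.38),
    ("sciatica", 0.17, -0.057, -0.31, -0.077, -0.36),
    ("neck_pain", 0.20, -0.029, -0.29, -0.025, -0.30),
    ("trouble_seeing", 0.15, -0.061, -0.29, -0.047, -0.27),
    ("dermatitis", 0.10, -0.044, -0.16, -0.030, -0.16),
    ("stomach_trouble", 0.15, -0.039, -0.29, -0.039, -0.29),
    ("trouble_hearing", 0.15, -0.014, -0.15, -0.009, -0.16),
    ("trouble_sleeping", 0.15, -0.152, -0.46, -0.065, -0.36),
]

#: Published intercepts and (adjusted) R^2 per outcome label.
PUBLISHED_INTERCEPTS = {"propr": 0.692, "eq5d": 0.974}
PUBLISHED_R2 = {"propr": 0.41, "eq5d": 0.39}

_STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def published_condition_effects() -> pd.DataFrame:
    """Printed per-condition estimates, indexed by canonical condition name."""
    df = pd.DataFrame(
        _PUBLISHED_ROWS,
        columns=["condition", "prevalence", "propr_beta", "propr_zero_order", "eq5d_beta", "eq5d_zero_order"],
    ).set_index("condition")
    return df


def significance_stars(p: float) -> str:
    for threshold, mark in _STAR_THRESHOLDS:
        if p < threshold:
            return mark
    return ""


@dataclass(frozen=True)
class ConditionFit:
    """Per-condition OLS coefficients and zero-order correlations for one outcome."""

    outcome: str
    coefficients: pd.Series
    zero_order: pd.Series
    pvalues: pd.Series
    std_errors: pd.Series
    intercept: float
    r2: float
    adj_r2: float
    n: int

    def __post_init__(self):
        if len(self.coefficients) != len(self.zero_order):
            raise ValidationError("coefficient and zero-order vectors must align")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta": self.coefficients,
                "zero_order_r": self.zero_order,
                "p": self.pvalues,
                "stars": self.pvalues.map(significance_stars),
            }
        )

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "intercept": self.intercept,
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "n": self.n,
            "conditions": self.to_frame().to_dict(orient="index"),
        }


def _rank_check(X: pd.DataFrame) -> None:
    """Raise RankDeficiencyError naming degenerate or collinear columns."""
    bad = [c for c in X.columns if X[c].nunique() <= 1]
    arr = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(arr)), arr])) < X.shape[1] + 1:
        if not bad:
            # name columns whose removal restores full rank
            for c in X.columns:
                rest = X.drop(columns=[c]).to_numpy(dtype=float)
                if np.linalg.matrix_rank(np.column_stack([np.ones(len(rest)), rest])) == X.shape[1]:
                    bad.append(c)
        raise RankDeficiencyError(bad or list(X.columns))
    if bad:
        raise RankDeficiencyError(bad)


def fit_condition_regression(
    table: pd.DataFrame,
    outcome: str,
    conditions=CONDITIONS,
) -> ConditionFit:
    """OLS of one utility outcome on all condition indicators simultaneously.

    ``outcome`` is a column name of ``table`` (e.g. ``eq5d_utility``).
    Complete-case per model; reports the coefficient, the zero-order
    correlation, the intercept and both R^2 forms.
    """
    conditions = list(conditions)
    missing = [c for c in [outcome, *conditions] if c not in table.columns]
    if missing:
        raise SchemaError(missing)
    sub = table[[outcome, *conditions]].dropna()
    if len(sub) <= len(conditions) + 1:
        raise InsufficientDataError(f"need more than {len(conditions) + 1} complete cases, have {len(sub)}")
    vals = sub[conditions]
    if not vals.isin([0, 1]).all().all():
        raise ValidationError("condition indicators must be binary 0/1")
    _rank_check(vals)
    y = sub[outcome].to_numpy(dtype=float)
    X = sm.add_constant(vals.to_numpy(dtype=float))
    res = sm.OLS(y, X).fit()
    zero_order = pd.Series(
        {c: stats.pearsonr(sub[c], y).statistic for c in conditions}, name="zero_order_r"
    )
    return ConditionFit(
        outcome=outcome,
        coefficients=pd.Series(res.params[1:], index=conditions, name="beta"),
        zero_order=zero_order,
        pvalues=pd.Series(res.pvalues[1:], index=conditions, name="p"),
        std_errors=pd.Series(res.bse[1:], index=conditions, name="se"),
        intercept=float(res.params[0]),
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        n=int(len(sub)),
    )


class ConditionRegression(RegressorMixin, BaseEstimator):
    """sklearn-style wrapper around :func:`fit_condition_regression`.

    fit(X, y) takes a DataFrame of binary indicator columns and a utility
    vector; fitted attributes expose the coefficient vector and diagnostics.
    """

    def __init__(self, conditions=CONDITIONS):
        self.conditions = conditions

    def fit(self, X: pd.DataFrame, y):
        if isinstance(X, pd.DataFrame):
            table = X.copy()
        else:
            table = pd.DataFrame(np.asarray(X), columns=list(self.conditions))
        table["_outcome"] = np.asarray(y, dtype=float)
        fit = fit_condition_regression(table, "_outcome", self.conditions)
        self.fit_ = fit
        self.coef_ = fit.coefficients.to_numpy()
        self.intercept_ = fit.intercept
        return self

    def predict(self, X) -> np.ndarray:
        vals = (X[list(self.conditions)] if isinstance(X, pd.DataFrame) else pd.DataFrame(X)).to_numpy(dtype=float)
        return self.intercept_ + vals @ self.coef_


def compare_coefficient_vectors(fit_a, fit_b) -> float:
    """Product-moment correlation between two aligned condition-coefficient vectors.

    Accepts :class:`ConditionFit` objects or named pandas Series; the
    condition name lists must match (order-insensitive).
    """
    a = fit_a.coefficients if isinstance(fit_a, ConditionFit) else pd.Series(fit_a)
    b = fit_b.coefficients if isinstance(fit_b, ConditionFit) else pd.Series(fit_b)
    if set(a.index) != set(b.index):
        raise ValidationError("condition name lists do not match")
    b = b.reindex(a.index)
    return float(np.corrcoef(a.to_numpy(dtype=float), b.to_numpy(dtype=float))[0, 1])


def change_correlations(
    baseline: pd.DataFrame,
    followup: pd.DataFrame,
    retrospective_items,
    utility_columns=("propr_utility", "eq5d_utility"),
    id_column: str = "person_id",
) -> dict:
    """Correlate six-month utility change with retrospective change ratings.

    ``change = followup - baseline`` per utility for persons present in both
    waves.  Returns a dict with the change-change correlation and a
    DataFrame of per-item correlations/p-values (NaN-flagged when a change
    score is constant).  Retrospective items are assumed scored so that
    higher = more positive change.
    """
    for col in (id_column, *utility_columns):
        if col not in baseline.columns:
            raise SchemaError([col], f"baseline missing column {col}")
        if col not in followup.columns:
            raise SchemaError([col], f"followup missing column {col}")
    merged = baseline[[id_column, *utility_columns]].merge(
        followup[[id_column, *utility_columns, *[c for c in retrospective_items if c in followup.columns]]],
        on=id_column,
        suffixes=("_t0", "_t1"),
    )
    if len(merged) == 0:
        raise InsufficientDataError("no linked person IDs across waves")
    changes = {}
    for col in utility_columns:
        changes[col] = (merged[f"{col}_t1"] - merged[f"{col}_t0"]).to_numpy()

    def _corr(x, y):
        keep = np.isfinite(x) & np.isfinite(y)
        if keep.sum() < 3 or np.std(x[keep]) == 0 or np.std(y[keep]) == 0:
            return np.nan, np.nan
        res = stats.pearsonr(x[keep], y[keep])
        return float(res.statistic), float(res.pvalue)

    cc_r, cc_p = _corr(changes[utility_columns[0]], changes[utility_columns[1]])
    rows = {}
    for item in retrospective_items:
        if item not in merged.columns:
            raise SchemaError([item], f"followup missing retrospective item {item}")
        iv = merged[item].to_numpy(dtype=float)
        row = {}
        for col in utility_columns:
            r, p = _corr(changes[col], iv)
            row[f"r_change_{col}"] = r
            row[f"p_change_{col}"] = p
        rows[item] = row
    return {
        "n": int(len(merged)),
        "change_change_r": cc_r,
        "change_change_p": cc_p,
        "items": pd.DataFrame.from_dict(rows, orient="index"),
    }
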