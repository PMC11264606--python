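"""Agreement and association statistics for paired utility scores.

The central tool is the two-way person x measure ANOVA on an (n, 2) paired
sample, from which both intraclass correlations are formed:

* consistency ICC (two-way mixed, single measure):
      ICC(C,1) = (MS_between - MS_within) / (MS_between + (k-1) MS_within)
* absolute-agreement ICC (two-way random, single measure):
      ICC(A,1) = (MS_between - MS_within)
                 / (MS_between + (k-1) MS_within + k (MS_time - MS_within) / n)

with k = 2 measures.  The absolute-agreement form penalizes a mean offset
between the measures (its large-n limit is the concordance correlation
2 r s1 s2 / (s1^2 + s2^2 + (m1-m2)^2), exposed here as a closed-form
cross-check); the consistency form does not.

Sample SDs use the n-1 denominator throughout, and all pairwise statistics
are complete-case.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError, UndefinedStatisticError, ValidationError


@dataclass(frozen=True)
class PairedSample:
    """Two aligned score vectors after complete-case filtering."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.ndim != 1 or y.ndim != 1 or len(x) != len(y):
            raise ValidationError("paired sample needs two 1-d vectors of equal length")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if len(x) < 2:
            raise InsufficientDataError("paired sample needs at least 2 complete cases")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValidationError("paired sample must be finite after complete-case filtering")

    @classmethod
    def from_arrays(cls, x, y) -> "PairedSample":
        """Build a complete-case sample, dropping rows with any missing value."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ValidationError("input vectors must have equal length")
        keep = np.isfinite(x) & np.isfinite(y)
        if keep.sum() < 2:
            raise InsufficientDataError("fewer than 2 complete cases")
        return cls(x[keep], y[keep])

    @property
    def n(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class AnovaDecomposition:
    """Mean squares of the two-way person x measure ANOVA (k = 2 measures)."""

    ms_between: float
    ms_within: float
    ms_time: float
    n: int
    k: int = 2

    def __post_init__(self):
        if min(self.ms_between, self.ms_within, self.ms_time) < -1e-12:
            raise ValidationError("mean squares must be non-negative")


@dataclass(frozen=True)
class AgreementReport:
    """Baseline agreement block between two utility measures."""

    pearson_r: float
    icc_mixed: float
    icc_random: float
    mean_difference: float
    mean_x: float
    mean_y: float
    sd_x: float
    sd_y: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def anova_decompose(sample: PairedSample) -> AnovaDecomposition:
    """Two-way person x measure ANOVA mean squares for an (n, 2) paired sample.

    Sums of squares are exactly conserved:
    SS_total = SS_between + SS_time + SS_within (interaction).
    """
    if not isinstance(sample, PairedSample):
        sample = PairedSample.from_arrays(*sample)
    data = np.column_stack([sample.x, sample.y])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_between = k * np.sum((row_means - grand) ** 2)
    ss_time = n * np.sum((col_means - grand) ** 2)
    resid = data - row_means[:, None] - col_means[None, :] + grand
    ss_within = np.sum(resid**2)
    return AnovaDecomposition(
        ms_between=ss_between / (n - 1),
        ms_within=ss_within / ((n - 1) * (k - 1)),
        ms_time=ss_time / (k - 1),
        n=n,
        k=k,
    )


def icc_two_way_mixed(decomp: AnovaDecomposition) -> float:
    """Two-way mixed-effects, single-measure, consistency ICC, ICC(C,1)."""
    msb, msw, k = decomp.ms_between, decomp.ms_within, decomp.k
    denom = msb + (k - 1) * msw
    if denom <= 0 or decomp.ms_between == 0:
        raise UndefinedStatisticError("consistency ICC undefined: zero between-person variance")
    return (msb - msw) / denom


def icc_two_way_random(decomp: AnovaDecomposition) -> float:
    """Two-way random-effects, single-measure, absolute-agreement ICC, ICC(A,1).

    Equivalent to the two-way mixed-effects absolute-agreement form; its
    large-n limit is the moment concordance correlation
    (see :func:`concordance_from_moments`).
    """
    msb, msw, mst = decomp.ms_between, decomp.ms_within, decomp.ms_time
    n, k = decomp.n, decomp.k
    denom = msb + (k - 1) * msw + k * (mst - msw) / n
    if denom <= 0:
        raise UndefinedStatisticError("absolute-agreement ICC undefined: degenerate denominator")
    return (msb - msw) / denom


def concordance_from_moments(mean_x, sd_x, mean_y, sd_y, r) -> float:
    """Closed-form concordance correlation 2 r s1 s2 / (s1^2 + s2^2 + (m1-m2)^2)."""
    denom = sd_x**2 + sd_y**2 + (mean_x - mean_y) ** 2
    if denom <= 0:
        raise UndefinedStatisticError("concordance undefined for degenerate moments")
    return 2.0 * r * sd_x * sd_y / denom


def nmae(observed, predicted) -> float:
    """Normalized mean absolute error: mean |obs - pred| / SD(obs), SD with n-1.

    Lower is better; scale-invariant (multiplying both vectors by k > 0
    leaves it unchanged).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValidationError("observed and predicted must be aligned")
    keep = np.isfinite(obs) & np.isfinite(pred)
    obs, pred = obs[keep], pred[keep]
    if len(obs) < 2:
        raise InsufficientDataError("NMAE needs at least 2 complete cases")
    sd = obs.std(ddof=1)
    if sd == 0:
        raise UndefinedStatisticError("NMAE undefined: observed scores are constant")
    return float(np.mean(np.abs(obs - pred)) / sd)


def cohen_d_to_r(d) -> float:
    """Convert a Cohen's d effect size to a point-biserial correlation.

    r = d / sqrt(d^2 + 4); odd in d, bounded in (-1, 1).  On this scale
    d = 0.2/0.5/0.8 (small/medium/large) map to r = 0.100/0.243/0.371.
    """
    d = np.asarray(d, dtype=float)
    out = d / np.sqrt(d**2 + 4.0)
    return float(out) if out.ndim == 0 else out


def correlation_matrix(table: pd.DataFrame, variables=None):
    """Pairwise complete-case product-moment correlations with two-sided p-values.

    Returns ``(r, p, n)`` DataFrames.  Pairs with a constant column or fewer
    than 3 complete cases are flagged undefined (NaN).
    """
    if variables is None:
        variables = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    missing = [v for v in variables if v not in table.columns]
    if missing:
        raise ValidationError(f"variables not in table: {', '.join(missing)}")
    m = len(variables)
    r = pd.DataFrame(np.eye(m), index=variables, columns=variables)
    p = pd.DataFrame(np.zeros((m, m)), index=variables, columns=variables)
    n = pd.DataFrame(np.zeros((m, m), dtype=int), index=variables, columns=variables)
    for i, a in enumerate(variables):
        xa = table[a].to_numpy(dtype=float)
        n.loc[a, a] = int(np.isfinite(xa).sum())
        for b in variables[i + 1 :]:
            xb = table[b].to_numpy(dtype=float)
            keep = np.isfinite(xa) & np.isfinite(xb)
            nn = int(keep.sum())
            n.loc[a, b] = n.loc[b, a] = nn
            if nn < 3 or np.std(xa[keep]) == 0 or np.std(xb[keep]) == 0:
                r.loc[a, b] = r.loc[b, a] = np.nan
                p.loc[a, b] = p.loc[b, a] = np.nan
                continue
            res = stats.pearsonr(xa[keep], xb[keep])
            r.loc[a, b] = r.loc[b, a] = res.statistic
            p.loc[a, b] = p.loc[b, a] = res.pvalue
    return r, p, n


def agreement_report(x, y) -> AgreementReport:
    """Full agreement block for two aligned score vectors (complete-case)."""
    sample = PairedSample.from_arrays(x, y)
    decomp = anova_decompose(sample)
    r = float(np.corrcoef(sample.x, sample.y)[0, 1])
    return AgreementReport(
        pearson_r=r,
        icc_mixed=icc_two_way_mixed(decomp),
        icc_random=icc_two_way_random(decomp),
        mean_difference=float(sample.x.mean() - sample.y.mean()),
        mean_x=float(sample.x.mean()),
        mean_y=float(sample.y.mean()),
        sd_x=float(sample.x.std(ddof=1)),
        sd_y=float(sample.y.std(ddof=1)),
        n=sample.n,
    )
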