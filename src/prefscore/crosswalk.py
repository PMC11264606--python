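"""Score mapping between the two utilities: OLS + linear equating + clamping.

A crosswalk is applied in three fixed stages:

1. predict:  yhat = a + b * x                        (OLS coefficients)
2. equate:   yeq  = m_t + (s_t / s_p) * (yhat - m_t) (match the observed
             target mean m_t and SD s_t; s_p is the SD of the predicted
             scores, so equating undoes regression-to-the-mean shrinkage)
3. clamp:    recode outside the instrument bounds to the nearest bound.

The published constants from the source study's general-population fit are
packaged (:func:`published_model`).  A beta-family alternative on the unit
interval is provided for comparison (:class:`BetaCrosswalkRegressor`),
either as a continuous beta regression with a logit mean link or as a
genuine beta-binomial with an integer trials denominator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace

import numpy as np
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator, RegressorMixin
import statsmodels.api as sm
from statsmodels.othermod.betareg import BetaModel

from .agreement import (
    PairedSample,
    anova_decompose,
    icc_two_way_random,
    nmae,
)
from .exceptions import (
    DegenerateFitError,
    FitFailureError,
    UndefinedStatisticError,
    ValidationError,
)

PROPR_TO_EQ5D = "propr_to_eq5d"
EQ5D_TO_PROPR = "eq5d_to_propr"
DIRECTIONS = (PROPR_TO_EQ5D, EQ5D_TO_PROPR)


@dataclass(frozen=True)
class CrosswalkModel:
    """Fitted (or packaged) linear crosswalk with its equating and clamp data."""

    direction: str
    intercept: float
    slope: float
    target_mean: float
    target_sd: float
    predicted_sd: float
    clamp_lower: float
    clamp_upper: float
    adj_r2: float | None = None
    n: int | None = None
    version: str = "1"

    def __post_init__(self):
        if self.target_sd <= 0 or self.predicted_sd <= 0:
            raise ValidationError("target and predicted SDs must be positive")
        if not self.clamp_lower < self.clamp_upper:
            raise ValidationError("clamp bounds must satisfy lower < upper")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CrosswalkModel":
        return cls(**json.loads(text))


#: Constants of the published general-population fits (3-dp printed precision).
#: The PROPr equating target mean is the 0.538 used in the published equating
#: equation (the same study prints 0.539 as the baseline descriptive mean).
_PUBLISHED = {
    PROPR_TO_EQ5D: CrosswalkModel(
        direction=PROPR_TO_EQ5D,
        intercept=0.563,
        slope=0.543,
        target_mean=0.855,
        target_sd=0.195,
        predicted_sd=0.135,
        clamp_lower=-0.573,
        clamp_upper=1.0,
        adj_r2=0.48,
        n=4092,
    ),
    EQ5D_TO_PROPR: CrosswalkModel(
        direction=EQ5D_TO_PROPR,
        intercept=-0.218,
        slope=0.885,
        target_mean=0.538,
        target_sd=0.249,
        predicted_sd=0.173,
        clamp_lower=-0.022,
        clamp_upper=1.0,
        adj_r2=0.48,
        n=4092,
    ),
}


def published_model(direction: str) -> CrosswalkModel:
    """The packaged published crosswalk constants for one mapping direction."""
    if direction not in _PUBLISHED:
        raise ValidationError(f"unknown direction {direction!r}; expected one of {DIRECTIONS}")
    return _PUBLISHED[direction]


def _clean_xy(source, target):
    x = np.asarray(source, dtype=float)
    y = np.asarray(target, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("source and target must be aligned 1-d vectors")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


class CrosswalkRegressor(RegressorMixin, BaseEstimator):
    """OLS crosswalk estimator with linear equating and clamping.

    Parameters
    ----------
    direction : str
        Label carried into the fitted :class:`CrosswalkModel`.
    clamp_bounds : tuple of float, optional
        Instrument bounds of the target scale.  Defaults to the observed
        range of the training target, matching the "nearest observed
        score" recoding rule.
    equate : bool
        If False, :meth:`predict` stops after the OLS stage.

    Attributes
    ----------
    intercept_, slope_ : float
    model_ : CrosswalkModel
    """

    def __init__(self, direction: str = "custom", clamp_bounds=None, equate: bool = True):
        self.direction = direction
        self.clamp_bounds = clamp_bounds
        self.equate = equate

    def fit(self, X, y):
        x, t = _clean_xy(np.ravel(X), y)
        if len(x) < 3:
            raise DegenerateFitError("crosswalk fit needs at least 3 complete pairs")
        if x.std() == 0:
            raise DegenerateFitError("source scores are constant; slope is unidentified")
        res = sm.OLS(t, sm.add_constant(x)).fit()
        predicted = res.fittedvalues
        lo, hi = self.clamp_bounds if self.clamp_bounds is not None else (t.min(), t.max())
        self.intercept_ = float(res.params[0])
        self.slope_ = float(res.params[1])
        self.model_ = CrosswalkModel(
            direction=self.direction,
            intercept=self.intercept_,
            slope=self.slope_,
            target_mean=float(t.mean()),
            target_sd=float(t.std(ddof=1)),
            predicted_sd=float(predicted.std(ddof=1)),
            clamp_lower=float(lo),
            clamp_upper=float(hi),
            adj_r2=float(res.rsquared_adj),
            n=int(len(x)),
        )
        return self

    def predict(self, X) -> np.ndarray:
        x = np.ravel(np.asarray(X, dtype=float))
        if self.equate:
            return apply_crosswalk(self.model_, x)
        return self.model_.intercept + self.model_.slope * x


def fit_ols_map(source, target, direction: str = "custom", clamp_bounds=None) -> CrosswalkModel:
    """Least-squares crosswalk from ``source`` to ``target`` scores."""
    return CrosswalkRegressor(direction=direction, clamp_bounds=clamp_bounds).fit(source, target).model_


def apply_crosswalk(model: CrosswalkModel, source, return_stages: bool = False):
    """Map source scores through the model: predict -> equate -> clamp (in that order)."""
    x = np.asarray(source, dtype=float)
    predicted = model.intercept + model.slope * x
    equated = model.target_mean + (model.target_sd / model.predicted_sd) * (predicted - model.target_mean)
    clamped = np.clip(equated, model.clamp_lower, model.clamp_upper)
    if return_stages:
        return predicted, equated, clamped
    return clamped


@dataclass(frozen=True)
class UnitIntervalTransform:
    """Affine map of observed scores onto [0, 1]; invertible via stored min/range."""

    minimum: float
    range_: float

    def __call__(self, scores):
        return (np.asarray(scores, dtype=float) - self.minimum) / self.range_

    def inverse(self, unit_scores):
        return self.minimum + self.range_ * np.asarray(unit_scores, dtype=float)


def to_unit_interval(scores):
    """Rescale scores to [0, 1] by (x - min) / range; returns (scaled, transform)."""
    x = np.asarray(scores, dtype=float)
    finite = x[np.isfinite(x)]
    if len(finite) == 0:
        raise ValidationError("no finite scores to rescale")
    rng = float(finite.max() - finite.min())
    if rng == 0:
        raise DegenerateFitError("observed range is zero; unit-interval rescaling undefined")
    tr = UnitIntervalTransform(minimum=float(finite.min()), range_=rng)
    return tr(x), tr


def _nudge_off_boundary(u, n):
    """Standard (y (n-1) + 0.5) / n compression keeping 0/1 off the open interval."""
    return (u * (n - 1) + 0.5) / n


class BetaCrosswalkRegressor(RegressorMixin, BaseEstimator):
    """Beta-family crosswalk on the unit-interval rescaled target.

    ``mode="beta"`` fits a continuous beta regression (logit mean link,
    precision parameter phi) via maximum likelihood; ``mode="beta-binomial"``
    rounds the rescaled target to counts out of ``trials`` and fits a true
    beta-binomial likelihood.  Predictions are pushed back through the
    inverse of the stored unit-interval transform, so :meth:`predict`
    returns scores on the original utility scale.

    By default the unit-interval transform is estimated from the observed
    target range; pass a :class:`UnitIntervalTransform` as ``transform`` to
    rescale against a pre-specified (e.g. theoretical) range instead.

    Attributes
    ----------
    params_ : dict with intercept, slope and dispersion
    bse_ : dict of standard errors (beta mode)
    transform_ : UnitIntervalTransform
    """

    def __init__(self, mode: str = "beta", trials: int = 100,
                 transform: UnitIntervalTransform | None = None):
        self.mode = mode
        self.trials = trials
        self.transform = transform

    def fit(self, X, y):
        if self.mode not in {"beta", "beta-binomial"}:
            raise ValidationError("mode must be 'beta' or 'beta-binomial'")
        x, t = _clean_xy(np.ravel(X), y)
        if len(x) < 4:
            raise DegenerateFitError("beta-family fit needs at least 4 complete pairs")
        if self.transform is not None:
            self.transform_ = self.transform
            u = np.clip(self.transform_(t), 0.0, 1.0)
        else:
            u, self.transform_ = to_unit_interval(t)
        exog = sm.add_constant(x)
        if self.mode == "beta":
            u = _nudge_off_boundary(u, len(u))
            try:
                res = BetaModel(u, exog).fit(disp=False)
            except Exception as exc:
                raise FitFailureError(f"beta regression failed: {exc}") from exc
            if not res.mle_retvals.get("converged", True):
                raise FitFailureError(f"beta regression did not converge: {res.mle_retvals}")
            self.params_ = {
                "intercept": float(res.params[0]),
                "slope": float(res.params[1]),
                "precision": float(np.exp(res.params[2])),
            }
            self.bse_ = {"intercept": float(res.bse[0]), "slope": float(res.bse[1])}
            self._result = res
        else:
            m = int(self.trials)
            counts = np.rint(u * m).astype(int)

            def negll(theta):
                a, b, logphi = theta
                mu = special.expit(a + b * x)
                phi = np.exp(logphi)
                return -np.sum(stats.betabinom.logpmf(counts, m, mu * phi, (1 - mu) * phi))

            start = np.array([special.logit(np.clip(u.mean(), 0.05, 0.95)), 0.0, np.log(5.0)])
            opt = optimize.minimize(negll, start, method="Nelder-Mead",
                                    options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-8})
            if not opt.success:
                raise FitFailureError(f"beta-binomial optimization failed: {opt.message}")
            self.params_ = {
                "intercept": float(opt.x[0]),
                "slope": float(opt.x[1]),
                "precision": float(np.exp(opt.x[2])),
            }
            self._result = opt
        return self

    def predict_unit(self, X) -> np.ndarray:
        x = np.ravel(np.asarray(X, dtype=float))
        return special.expit(self.params_["intercept"] + self.params_["slope"] * x)

    def predict(self, X) -> np.ndarray:
        return self.transform_.inverse(self.predict_unit(X))


def fit_beta_binomial_map(source, target, mode: str = "beta", trials: int = 100,
                          transform: UnitIntervalTransform | None = None) -> BetaCrosswalkRegressor:
    """Fit the beta-family crosswalk; see :class:`BetaCrosswalkRegressor`."""
    return BetaCrosswalkRegressor(mode=mode, trials=trials, transform=transform).fit(source, target)


@dataclass(frozen=True)
class MapEvaluation:
    """Fit-quality block: adjusted R^2 plus agreement of equated vs observed."""

    adj_r2: float
    pearson_r: float
    icc_random: float
    nmae: float
    equated_mean: float
    equated_sd: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate_predictions(observed, mapped, n_params: int = 2) -> MapEvaluation:
    """Evaluate mapped-vs-observed scores (works for OLS and beta-family maps)."""
    sample = PairedSample.from_arrays(observed, mapped)
    r = float(np.corrcoef(sample.x, sample.y)[0, 1])
    n = sample.n
    r2 = r**2
    adj = 1 - (1 - r2) * (n - 1) / (n - n_params)
    icc = icc_two_way_random(anova_decompose(sample))
    return MapEvaluation(
        adj_r2=float(adj),
        pearson_r=r,
        icc_random=float(icc),
        nmae=nmae(sample.x, sample.y),
        equated_mean=float(sample.y.mean()),
        equated_sd=float(sample.y.std(ddof=1)),
        n=n,
    )


def evaluate_map(model: CrosswalkModel, source, observed_target) -> MapEvaluation:
    """Apply the crosswalk to ``source`` and score it against the observed target.

    ``adj_r2`` is taken from the model's own fit diagnostics when available
    (the regression's adjusted R^2); otherwise it is recomputed from the
    squared correlation between mapped and observed scores.
    """
    x, t = _clean_xy(source, observed_target)
    mapped = apply_crosswalk(model, x)
    ev = evaluate_predictions(t, mapped)
    if model.adj_r2 is not None:
        ev = replace(ev, adj_r2=float(model.adj_r2))
    return ev
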