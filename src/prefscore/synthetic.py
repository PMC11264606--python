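"""Synthetic baseline and six-month cohorts with the study's statistical structure.

This module is explicitly a stand-in for the survey data: it reproduces the
published summary structure — marginal utility moments, the EQ-5D-5L
ceiling fraction, the cross-measure correlation, condition prevalences and
effects, and the longitudinal change correlation — not the full shape of
real preference-score distributions.

Generating mechanism
--------------------
* The 22 condition indicators are drawn independently at their published
  prevalences (two fake screening conditions are emitted as all-zero
  columns).
* Latent utilities are linear in the conditions (published coefficients as
  true effects) plus correlated Gaussian noise.
* The observed EQ-5D-5L applies a latent-threshold ceiling: latents at or
  above a calibrated threshold c map to exactly 1; the rest are capped at
  the second-best observable utility (default 0.94) and floored at the
  instrument minimum.  A plain right-censored Gaussian cannot reach the
  published mean/SD/ceiling triple simultaneously, so the threshold is a
  free calibration parameter.
* The observed PROPr clamps a Gaussian latent to its theoretical range.
* :func:`calibrate` numerically solves latent means/SDs/threshold and the
  latent correlation so the post-censoring moments hit the spec targets;
  the follow-up change distribution is calibrated the same way by a
  fixed-seed internal Monte-Carlo root-find.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .condition_models import CONDITIONS, FAKE_CONDITIONS, PUBLISHED_INTERCEPTS, published_condition_effects
from .exceptions import CalibrationError, InsufficientDataError, ValidationError
from .pain_instruments import classify_chronic_pain

#: retrospective-change item columns (scored so higher = more positive change)
RETRO_ITEMS = (
    "retro_physical_function",
    "retro_social",
    "retro_pain",
    "retro_fatigue",
    "retro_mood",
    "retro_cognition",
    "retro_sleep",
    "retro_health",
    "retro_back_pain",
)

#: published fraction answering "About the same" per retrospective item
_RETRO_SAME = {
    "retro_physical_function": 0.65,
    "retro_social": 0.76,
    "retro_pain": 0.62,
    "retro_fatigue": 0.65,
    "retro_mood": 0.66,
    "retro_cognition": 0.76,
    "retro_sleep": 0.66,
    "retro_health": 0.64,
    "retro_back_pain": 0.58,
}

#: target correlation of each item with utility change (average of the two
#: published per-measure values)
_RETRO_TARGETS = {
    "retro_physical_function": 0.16,
    "retro_social": 0.15,
    "retro_pain": 0.175,
    "retro_fatigue": 0.135,
    "retro_mood": 0.105,
    "retro_cognition": 0.075,
    "retro_sleep": 0.12,
    "retro_health": 0.16,
    "retro_back_pain": 0.15,
}

#: instrument -> (|target correlation with utilities|, mean, sd, lo, hi, step)
#: marginal means/SDs are community back-pain values (package choice)
_PAIN_TARGETS = {
    "odi": (0.72, 22.0, 16.0, 0.0, 100.0, 2.0),
    "rmdq": (0.635, 7.0, 5.5, 0.0, 24.0, 1.0),
    "peg": (0.695, 3.5, 2.4, 0.0, 10.0, 1.0 / 3.0),
    "startback": (0.66, 3.0, 2.2, 0.0, 9.0, 1.0),
    "gcps_intensity": (0.565, 40.0, 22.0, 0.0, 100.0, 10.0 / 3.0),
    "gcps_disability": (0.665, 30.0, 25.0, 0.0, 100.0, 10.0 / 3.0),
}

_INTERNAL_MC_SEED = 20220922  # fixed: calibration must not depend on the user seed
_LATENT_COLUMNS = ("eq5d_latent", "propr_latent")


@dataclass
class CohortSpec:
    """Calibration targets and sizes for the synthetic cohort generator.

    Defaults are the published study conditions: n = 4,098 baseline with
    EQ-5D-5L mean 0.855 / SD 0.195 (31% ceiling), PROPr mean 0.539 /
    SD 0.249, cross-measure correlation 0.69; a back-pain follow-up subset
    of n = 1,256 with change-score correlation 0.34.
    """

    n_baseline: int = 4098
    n_followup: int = 1256
    eq5d_mean: float = 0.855
    eq5d_sd: float = 0.195
    propr_mean: float = 0.539
    propr_sd: float = 0.249
    utility_correlation: float = 0.69
    eq5d_ceiling: float = 0.31
    eq5d_min: float = -0.573
    eq5d_max: float = 1.0
    eq5d_second_best: float = 0.94
    propr_min: float = -0.022
    propr_max: float = 0.954
    condition_effects: pd.DataFrame = field(default_factory=published_condition_effects)
    condition_intercepts: dict = field(default_factory=lambda: dict(PUBLISHED_INTERCEPTS))
    change_sd_eq5d: float = 0.13
    change_sd_propr: float = 0.19
    change_correlation: float = 0.34
    retro_same_fractions: dict = field(default_factory=lambda: dict(_RETRO_SAME))
    retro_correlation_targets: dict = field(default_factory=lambda: dict(_RETRO_TARGETS))
    pain_targets: dict = field(default_factory=lambda: dict(_PAIN_TARGETS))
    seed: int | None = None

    def validate(self) -> None:
        if self.eq5d_sd <= 0 or self.propr_sd <= 0:
            raise CalibrationError("utility SD targets must be positive")
        if not 0 <= self.eq5d_ceiling < 1:
            raise CalibrationError("ceiling fraction must lie in [0, 1)")
        if not -1 <= self.utility_correlation <= 1 or not -1 <= self.change_correlation <= 1:
            raise CalibrationError("correlation targets must lie in [-1, 1]")
        if self.change_sd_eq5d < 0 or self.change_sd_propr < 0:
            raise CalibrationError("change SDs must be non-negative")
        if (self.change_sd_eq5d == 0 or self.change_sd_propr == 0) and self.change_correlation != 0:
            raise CalibrationError("zero change SD is contradictory with a nonzero change correlation")
        for frac in self.retro_same_fractions.values():
            if not 0 <= frac <= 1:
                raise CalibrationError("retrospective 'same' fractions must lie in [0, 1]")
        missing = [c for c in CONDITIONS if c not in self.condition_effects.index]
        if missing:
            raise ValidationError(f"condition_effects missing rows: {', '.join(missing)}")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["condition_effects"] = self.condition_effects.reset_index().to_dict(orient="list")
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CohortSpec":
        d = json.loads(text)
        ce = d.get("condition_effects")
        if ce is not None:
            d["condition_effects"] = pd.DataFrame(ce).set_index("condition")
        return cls(**d)

    def _fingerprint(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("seed", None)
        d.pop("n_baseline", None)
        d.pop("n_followup", None)
        d["condition_effects"] = self.condition_effects.round(12).to_csv()
        return json.dumps(d, sort_keys=True, default=str)


@dataclass(frozen=True)
class CohortCalibration:
    """Latent-scale parameters solved from a :class:`CohortSpec`."""

    eq_mu: float
    eq_sigma: float
    eq_threshold: float
    propr_mu: float
    propr_sigma: float
    latent_correlation: float
    noise_sd_eq: float
    noise_sd_propr: float
    noise_correlation: float
    noise_shift_eq: float
    noise_shift_propr: float
    change_drift_eq: float
    change_drift_propr: float
    change_latent_correlation: float
    report: dict


def _eq_transform(latent, spec: CohortSpec, calib_threshold: float):
    latent = np.asarray(latent, dtype=float)
    # without a ceiling mechanism the cap is the instrument maximum itself
    cap = spec.eq5d_second_best if np.isfinite(calib_threshold) else spec.eq5d_max
    capped = np.clip(latent, spec.eq5d_min, cap)
    return np.where(latent >= calib_threshold, spec.eq5d_max, capped)


def _propr_transform(latent, spec: CohortSpec):
    return np.clip(np.asarray(latent, dtype=float), spec.propr_min, spec.propr_max)


_GRID = np.linspace(-8.5, 8.5, 8193)
_GRID_PDF = stats.norm.pdf(_GRID)


def _margin_moments(transform, mu, sigma):
    """Mean, SD and a raw-second-moment of transform(N(mu, sigma)) by quadrature."""
    y = transform(mu + sigma * _GRID)
    m = np.trapezoid(y * _GRID_PDF, _GRID)
    m2 = np.trapezoid(y**2 * _GRID_PDF, _GRID)
    return m, float(np.sqrt(max(m2 - m**2, 0.0)))


def _solve_eq_latent(spec: CohortSpec):
    """Latent (mu, sigma, threshold) matching EQ-5D-5L mean, SD and ceiling."""
    if spec.eq5d_ceiling == 0:
        # no ceiling mechanism: latent Gaussian used directly (clamped to range)
        return spec.eq5d_mean, spec.eq5d_sd, np.inf

    def eqs(p):
        mu, sigma, c = p
        if sigma <= 0:
            return [1e3, 1e3, 1e3]
        tr = lambda l: _eq_transform(l, spec, c)
        m, s = _margin_moments(tr, mu, sigma)
        ceiling = 1 - stats.norm.cdf((c - mu) / sigma)
        return [ceiling - spec.eq5d_ceiling, m - spec.eq5d_mean, s - spec.eq5d_sd]

    start = [spec.eq5d_mean + 0.2, spec.eq5d_sd + 0.1, spec.eq5d_max + 0.15]
    sol, info, ier, msg = optimize.fsolve(eqs, start, full_output=True, xtol=1e-12)
    if np.max(np.abs(info["fvec"])) > 1e-8:
        raise CalibrationError(f"EQ-5D-5L latent calibration failed: {msg}", residuals=info["fvec"])
    return float(sol[0]), float(sol[1]), float(sol[2])


def _solve_propr_latent(spec: CohortSpec):
    def eqs(p):
        mu, sigma = p
        if sigma <= 0:
            return [1e3, 1e3]
        m, s = _margin_moments(lambda l: _propr_transform(l, spec), mu, sigma)
        return [m - spec.propr_mean, s - spec.propr_sd]

    sol, info, ier, msg = optimize.fsolve(eqs, [spec.propr_mean, spec.propr_sd], full_output=True, xtol=1e-12)
    if np.max(np.abs(info["fvec"])) > 1e-8:
        raise CalibrationError(f"PROPr latent calibration failed: {msg}", residuals=info["fvec"])
    return float(sol[0]), float(sol[1])


def _clipped_normal_mean(m, s, a, b):
    """E[clip(X, a, b)] for X ~ N(m, s); s may be 0 or an array."""
    m = np.asarray(m, dtype=float)
    if np.all(s == 0):
        return np.clip(m, a, b)
    alpha = (a - m) / s
    beta = (b - m) / s
    return (
        a * stats.norm.cdf(alpha)
        + b * stats.norm.sf(beta)
        + m * (stats.norm.cdf(beta) - stats.norm.cdf(alpha))
        - s * (stats.norm.pdf(beta) - stats.norm.pdf(alpha))
    )


def _observed_correlation(spec, eq_mu, eq_sig, eq_c, p_mu, p_sig, rho):
    """corr(observed EQ, observed PROPr) for latent correlation rho.

    Semi-analytic: the PROPr clamp is integrated out in closed form
    conditional on the EQ latent; the remaining 1-d integral (which carries
    the EQ transform's jump) runs on a dense grid.
    """
    l1 = eq_mu + eq_sig * _GRID
    y1 = _eq_transform(l1, spec, eq_c)
    cond_m = p_mu + rho * (p_sig / eq_sig) * (l1 - eq_mu)
    cond_s = p_sig * np.sqrt(max(1 - rho**2, 0.0))
    m2_cond = _clipped_normal_mean(cond_m, cond_s, spec.propr_min, spec.propr_max)
    e12 = np.trapezoid(y1 * m2_cond * _GRID_PDF, _GRID)
    m1, s1 = _margin_moments(lambda l: _eq_transform(l, spec, eq_c), eq_mu, eq_sig)
    m2, s2 = _margin_moments(lambda l: _propr_transform(l, spec), p_mu, p_sig)
    return (e12 - m1 * m2) / (s1 * s2)


def _solve_latent_correlation(spec, eq_mu, eq_sig, eq_c, p_mu, p_sig):
    target = spec.utility_correlation
    if target == 0:
        return 0.0
    f = lambda r: _observed_correlation(spec, eq_mu, eq_sig, eq_c, p_mu, p_sig, r) - target
    lo, hi = (1e-6, 1 - 1e-9) if target > 0 else (-1 + 1e-9, -1e-6)
    try:
        return float(optimize.brentq(f, lo, hi, xtol=1e-10))
    except ValueError as exc:
        raise CalibrationError(f"cross-measure correlation target {target} is infeasible") from exc


def _condition_moments(spec: CohortSpec):
    """Mean/variance/covariance of the systematic (condition-driven) parts."""
    eff = spec.condition_effects.loc[list(CONDITIONS)]
    p = eff["prevalence"].to_numpy(dtype=float)
    be = eff["eq5d_beta"].to_numpy(dtype=float)
    bp = eff["propr_beta"].to_numpy(dtype=float)
    pq = p * (1 - p)
    return {
        "mean_eq": spec.condition_intercepts["eq5d"] + float(p @ be),
        "mean_propr": spec.condition_intercepts["propr"] + float(p @ bp),
        "var_eq": float(pq @ be**2),
        "var_propr": float(pq @ bp**2),
        "cov": float(pq @ (be * bp)),
    }


def _solve_change(spec: CohortSpec, eq_mu, eq_sig, eq_c, p_mu, p_sig, rho, sys_m):
    """Fixed-seed MC root-find for change drifts and latent change correlation.

    The back-pain subpopulation (on which follow-up is observed) has a
    shifted latent distribution, so the MC draws conditions and filters to
    back-pain = 1 before calibrating.
    """
    if spec.change_sd_eq5d == 0 and spec.change_sd_propr == 0:
        return 0.0, 0.0, 0.0
    rng = np.random.default_rng(_INTERNAL_MC_SEED)
    m = 300_000
    eff = spec.condition_effects.loc[list(CONDITIONS)]
    prev = eff["prevalence"].to_numpy(dtype=float)
    X = (rng.random((m, len(CONDITIONS))) < prev).astype(float)
    sys_eq = spec.condition_intercepts["eq5d"] + X @ eff["eq5d_beta"].to_numpy(dtype=float)
    sys_pr = spec.condition_intercepts["propr"] + X @ eff["propr_beta"].to_numpy(dtype=float)
    noise = _noise_params(spec, eq_sig, p_sig, rho, sys_m)
    e = rng.standard_normal((m, 2))
    e2 = noise["corr"] * e[:, 0] + np.sqrt(1 - noise["corr"] ** 2) * e[:, 1]
    L1 = sys_eq + (eq_mu - sys_m["mean_eq"]) + noise["sd_eq"] * e[:, 0]
    L2 = sys_pr + (p_mu - sys_m["mean_propr"]) + noise["sd_propr"] * e2
    bp = X[:, list(CONDITIONS).index("back_pain")] == 1
    L1, L2 = L1[bp], L2[bp]
    g1, g2 = rng.standard_normal((2, len(L1)))
    y1_0 = _eq_transform(L1, spec, eq_c)
    y2_0 = _propr_transform(L2, spec)

    def mean_change_eq(drift):
        y1 = _eq_transform(L1 + drift + spec.change_sd_eq5d * g1, spec, eq_c)
        return np.mean(y1 - y1_0)

    def mean_change_pr(drift, gg):
        y2 = _propr_transform(L2 + drift + spec.change_sd_propr * gg, spec)
        return np.mean(y2 - y2_0)

    drift_eq = optimize.brentq(mean_change_eq, -0.3, 0.3, xtol=1e-8) if spec.change_sd_eq5d > 0 else 0.0

    def solve_rho():
        target = spec.change_correlation
        if target == 0 or spec.change_sd_eq5d == 0 or spec.change_sd_propr == 0:
            return 0.0, optimize.brentq(lambda d: mean_change_pr(d, g2), -0.3, 0.3, xtol=1e-8)

        def f(r):
            gg = r * g1 + np.sqrt(1 - r**2) * g2
            dpr = optimize.brentq(lambda d: mean_change_pr(d, gg), -0.3, 0.3, xtol=1e-8)
            d1 = _eq_transform(L1 + drift_eq + spec.change_sd_eq5d * g1, spec, eq_c) - y1_0
            d2 = _propr_transform(L2 + dpr + spec.change_sd_propr * gg, spec) - y2_0
            return np.corrcoef(d1, d2)[0, 1] - target, dpr

        lo, hi = (1e-6, 1 - 1e-6) if target > 0 else (-1 + 1e-6, -1e-6)
        try:
            r = optimize.brentq(lambda r: f(r)[0], lo, hi, xtol=1e-6)
        except ValueError as exc:
            raise CalibrationError(f"change-correlation target {target} is infeasible") from exc
        return float(r), float(f(r)[1])

    rho_delta, drift_pr = solve_rho()
    return float(drift_eq), float(drift_pr), float(rho_delta)


def _noise_params(spec, eq_sig, p_sig, rho, sys_m):
    var_eq = eq_sig**2 - sys_m["var_eq"]
    var_pr = p_sig**2 - sys_m["var_propr"]
    if var_eq <= 0 or var_pr <= 0:
        raise CalibrationError("condition effects imply more variance than the utility SD targets allow")
    need_cov = rho * eq_sig * p_sig - sys_m["cov"]
    corr = need_cov / np.sqrt(var_eq * var_pr)
    if not -1 <= corr <= 1:
        raise CalibrationError(f"implied noise correlation {corr:.3f} outside [-1, 1]")
    return {"sd_eq": float(np.sqrt(var_eq)), "sd_propr": float(np.sqrt(var_pr)), "corr": float(corr)}


_CALIBRATION_CACHE: dict[str, CohortCalibration] = {}


def calibrate(spec: CohortSpec | None = None) -> CohortCalibration:
    """Solve all latent parameters for a spec; results are cached per spec.

    The returned report logs achieved vs target moments (achieved values
    are computed by numerical integration over the latent model, not by
    sampling).
    """
    spec = spec or CohortSpec()
    spec.validate()
    key = spec._fingerprint()
    if key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[key]
    eq_mu, eq_sig, eq_c = _solve_eq_latent(spec)
    p_mu, p_sig = _solve_propr_latent(spec)
    rho = _solve_latent_correlation(spec, eq_mu, eq_sig, eq_c, p_mu, p_sig)
    sys_m = _condition_moments(spec)
    noise = _noise_params(spec, eq_sig, p_sig, rho, sys_m)
    drift_eq, drift_pr, rho_delta = _solve_change(spec, eq_mu, eq_sig, eq_c, p_mu, p_sig, rho, sys_m)

    ach_eq = _margin_moments(lambda l: _eq_transform(l, spec, eq_c), eq_mu, eq_sig)
    ach_pr = _margin_moments(lambda l: _propr_transform(l, spec), p_mu, p_sig)
    ach_ceiling = float(1 - stats.norm.cdf((eq_c - eq_mu) / eq_sig)) if np.isfinite(eq_c) else 0.0
    ach_rho = _observed_correlation(spec, eq_mu, eq_sig, eq_c, p_mu, p_sig, rho)
    report = {
        "eq5d_mean": {"target": spec.eq5d_mean, "achieved": float(ach_eq[0])},
        "eq5d_sd": {"target": spec.eq5d_sd, "achieved": float(ach_eq[1])},
        "eq5d_ceiling": {"target": spec.eq5d_ceiling, "achieved": ach_ceiling},
        "propr_mean": {"target": spec.propr_mean, "achieved": float(ach_pr[0])},
        "propr_sd": {"target": spec.propr_sd, "achieved": float(ach_pr[1])},
        "utility_correlation": {"target": spec.utility_correlation, "achieved": float(ach_rho)},
    }
    calib = CohortCalibration(
        eq_mu=eq_mu,
        eq_sigma=eq_sig,
        eq_threshold=eq_c,
        propr_mu=p_mu,
        propr_sigma=p_sig,
        latent_correlation=rho,
        noise_sd_eq=noise["sd_eq"],
        noise_sd_propr=noise["sd_propr"],
        noise_correlation=noise["corr"],
        noise_shift_eq=eq_mu - sys_m["mean_eq"],
        noise_shift_propr=p_mu - sys_m["mean_propr"],
        change_drift_eq=drift_eq,
        change_drift_propr=drift_pr,
        change_latent_correlation=rho_delta,
        report=report,
    )
    _CALIBRATION_CACHE[key] = calib
    return calib


def _round_to_step(x, step):
    return np.round(np.asarray(x, dtype=float) / step) * step


def _pain_scores(spec, rng, severity):
    """Instrument scores driven by a shared latent severity (higher = worse)."""
    out = {}
    for name, (target, mean, sd, lo, hi, step) in spec.pain_targets.items():
        lam = min(target / 0.92, 0.97)
        lat = lam * severity + np.sqrt(1 - lam**2) * rng.standard_normal(len(severity))
        out[name] = np.clip(_round_to_step(mean + sd * lat, step), lo, hi)
    dur_lat = 0.75 * severity + np.sqrt(1 - 0.75**2) * rng.standard_normal(len(severity))
    freq_lat = 0.75 * severity + np.sqrt(1 - 0.75**2) * rng.standard_normal(len(severity))
    out["pain_duration_ge_3mo"] = (dur_lat > stats.norm.ppf(1 - 0.65)).astype(float)
    out["pain_half_days_6mo"] = (freq_lat > stats.norm.ppf(1 - 0.55)).astype(float)
    out["chronic_back_pain"] = classify_chronic_pain(out["pain_duration_ge_3mo"], out["pain_half_days_6mo"])
    return out


def generate_baseline(
    spec: CohortSpec | None = None,
    n: int | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Generate a baseline cohort table.

    Columns: person_id, the 22 condition indicators plus the two all-zero
    fake screening conditions, observed utilities, latent utilities
    (``eq5d_latent`` / ``propr_latent``, needed to build follow-up), the
    back-pain flag, and pain-instrument scores (non-missing only for the
    back-pain subgroup).
    """
    spec = spec or CohortSpec()
    calib = calibrate(spec)
    if rng is None:
        rng = np.random.default_rng(seed if seed is not None else spec.seed)
    n = int(n if n is not None else spec.n_baseline)
    eff = spec.condition_effects.loc[list(CONDITIONS)]
    prev = eff["prevalence"].to_numpy(dtype=float)
    X = (rng.random((n, len(CONDITIONS))) < prev).astype(int)
    sys_eq = spec.condition_intercepts["eq5d"] + X @ eff["eq5d_beta"].to_numpy(dtype=float)
    sys_pr = spec.condition_intercepts["propr"] + X @ eff["propr_beta"].to_numpy(dtype=float)
    e = rng.standard_normal((n, 2))
    e2 = calib.noise_correlation * e[:, 0] + np.sqrt(1 - calib.noise_correlation**2) * e[:, 1]
    eq_latent = sys_eq + calib.noise_shift_eq + calib.noise_sd_eq * e[:, 0]
    propr_latent = sys_pr + calib.noise_shift_propr + calib.noise_sd_propr * e2
    table = pd.DataFrame(X, columns=list(CONDITIONS))
    table.insert(0, "person_id", np.arange(n, dtype=int))
    for fake in FAKE_CONDITIONS:
        table[fake] = 0
    table["eq5d_latent"] = eq_latent
    table["propr_latent"] = propr_latent
    table["eq5d_utility"] = _eq_transform(eq_latent, spec, calib.eq_threshold)
    table["propr_utility"] = _propr_transform(propr_latent, spec)
    table["back_pain_flag"] = table["back_pain"].astype(int)

    for col in [*spec.pain_targets, "pain_duration_ge_3mo", "pain_half_days_6mo", "chronic_back_pain"]:
        table[col] = np.nan
    bp = table["back_pain_flag"] == 1
    if bp.any():
        z1 = (eq_latent - eq_latent.mean()) / eq_latent.std()
        z2 = (propr_latent - propr_latent.mean()) / propr_latent.std()
        health = (z1 + z2) / np.sqrt(2 * (1 + np.corrcoef(z1, z2)[0, 1]))
        severity = -health[bp.to_numpy()]
        for name, vals in _pain_scores(spec, rng, severity).items():
            table.loc[bp, name] = vals
    return table


def _retro_scores(spec, rng, composite, item):
    """Ordinal retrospective-change score (higher = more positive change)."""
    p_same = spec.retro_same_fractions[item]
    target = spec.retro_correlation_targets[item]
    rho_delta = max(spec.change_correlation, -0.999)
    # attenuation: composite -> each change score, then latent -> ordinal score
    comp_att = np.sqrt((1 + rho_delta) / 2)
    tau1 = stats.norm.ppf(0.5 + p_same / 2)
    n_cat_better = 4 if item == "retro_back_pain" else 2
    tail = (1 - p_same) / 2
    worse_splits = np.array([0.7, 0.3])
    better_splits = np.array([0.45, 0.3, 0.17, 0.08])[:n_cat_better]
    better_splits = better_splits / better_splits.sum()
    # cutpoints above tau1 for the better side, below -tau1 for the worse side
    ups = stats.norm.ppf(0.5 + p_same / 2 + tail * np.cumsum(better_splits)[:-1])
    downs = -stats.norm.ppf(0.5 + p_same / 2 + tail * np.cumsum(worse_splits)[:-1])
    cuts = np.concatenate([[-np.inf], np.sort(np.r_[downs, -tau1, tau1, ups]), [np.inf]])
    scores = np.arange(-2, n_cat_better + 1)  # worse..same(0)..better
    # ordinal attenuation of the latent -> score mapping
    inner = cuts[1:-1]
    probs = np.diff(stats.norm.cdf(cuts))
    mean_s = probs @ scores
    sd_s = np.sqrt(probs @ (scores - mean_s) ** 2)
    cross = np.sum(scores * np.diff(-stats.norm.pdf(cuts, 0, 1)))
    ord_att = cross / sd_s if sd_s > 0 else 1.0
    lam = float(np.clip(target / max(comp_att * ord_att, 1e-9), -0.99, 0.99))
    lat = lam * composite + np.sqrt(1 - lam**2) * rng.standard_normal(len(composite))
    return scores[np.searchsorted(inner, lat, side="right")]


def generate_followup(
    baseline: pd.DataFrame,
    spec: CohortSpec | None = None,
    n: int | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Six-month follow-up table for a back-pain subset of a baseline cohort.

    Follow-up utilities are the baseline latents plus a calibrated
    mean-zero (on the observed scale) bivariate change, pushed through the
    same censoring transforms.  Nine ordinal retrospective-change items are
    drawn with the published "About the same" mass and correlations with
    true change near the published values.
    """
    spec = spec or CohortSpec()
    calib = calibrate(spec)
    if rng is None:
        rng = np.random.default_rng(seed if seed is not None else spec.seed)
    missing = [c for c in (*_LATENT_COLUMNS, "back_pain_flag", "person_id") if c not in baseline.columns]
    if missing:
        raise ValidationError(f"baseline table missing columns: {', '.join(missing)}")
    pool = baseline.loc[baseline["back_pain_flag"] == 1]
    if len(pool) == 0:
        raise InsufficientDataError("baseline has no back-pain respondents")
    n = int(n if n is not None else spec.n_followup)
    if n > len(pool):
        raise InsufficientDataError(f"requested {n} follow-up rows but only {len(pool)} back-pain respondents")
    take = pool.iloc[np.sort(rng.choice(len(pool), size=n, replace=False))]

    g1, g2 = rng.standard_normal((2, n))
    rho_d = calib.change_latent_correlation
    d_eq = calib.change_drift_eq + spec.change_sd_eq5d * g1
    d_pr = calib.change_drift_propr + spec.change_sd_propr * (rho_d * g1 + np.sqrt(1 - rho_d**2) * g2)
    eq_lat = take["eq5d_latent"].to_numpy() + d_eq
    pr_lat = take["propr_latent"].to_numpy() + d_pr
    out = pd.DataFrame(
        {
            "person_id": take["person_id"].to_numpy(),
            "eq5d_latent": eq_lat,
            "propr_latent": pr_lat,
            "eq5d_utility": _eq_transform(eq_lat, spec, calib.eq_threshold),
            "propr_utility": _propr_transform(pr_lat, spec),
        }
    )
    delta_eq = out["eq5d_utility"].to_numpy() - take["eq5d_utility"].to_numpy()
    delta_pr = out["propr_utility"].to_numpy() - take["propr_utility"].to_numpy()
    sds = (delta_eq.std(), delta_pr.std())
    if sds[0] > 0 and sds[1] > 0:
        z1 = (delta_eq - delta_eq.mean()) / sds[0]
        z2 = (delta_pr - delta_pr.mean()) / sds[1]
        composite = (z1 + z2) / np.sqrt(2 * (1 + np.corrcoef(z1, z2)[0, 1]))
    else:
        composite = np.zeros(n)
    for item in RETRO_ITEMS:
        out[item] = _retro_scores(spec, rng, composite, item)
    return out


def bivariate_moment_sample(
    n: int,
    mean_x: float,
    sd_x: float,
    mean_y: float,
    sd_y: float,
    r: float,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    exact: bool = True,
):
    """Bivariate normal sample whose *sample* moments equal the targets.

    With ``exact=True`` the draw is centred, whitened against its own sample
    covariance (n-1 denominator) and recoloured to the target moments, so
    the sample means, SDs and correlation match the targets to machine
    precision; statistics that depend only on these moments are then
    deterministic regardless of seed.
    """
    if not -1 < r < 1:
        raise ValidationError("correlation must lie strictly inside (-1, 1)")
    if sd_x <= 0 or sd_y <= 0:
        raise ValidationError("SDs must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    z = rng.standard_normal((int(n), 2))
    if exact:
        z = z - z.mean(axis=0)
        chol = np.linalg.cholesky(np.cov(z, rowvar=False, ddof=1))
        z = z @ np.linalg.inv(chol).T
    z = z @ np.linalg.cholesky(np.array([[1.0, r], [r, 1.0]])).T
    x = mean_x + sd_x * z[:, 0]
    y = mean_y + sd_y * z[:, 1]
    return x, y
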