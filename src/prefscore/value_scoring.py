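"""Preference-based scoring of EQ-5D-5L health states and PROPr domain profiles.

Both instruments yield a single utility on the QALY scale (0 = dead,
1 = full health; states worse than dead are negative).  The EQ-5D-5L is
scored additively: a full-health anchor minus one tariff decrement per
item/level.  The PROPr is scored with a multiplicative multi-attribute
utility (MAUT) function: per-domain disutilities on [0, 1] are combined as

    1 + C*u  =  prod_j (1 + C * c_j * u_j)

where ``c_j`` are domain weights and ``C`` is the scaling constant solving
``prod_j (1 + C*c_j) = 1 + C``, and the aggregate disutility ``u`` is mapped
affinely onto the instrument's declared [min, max].

Value sets are plain-text config data (see :func:`load_value_set`), so the
engines are generic: any tariff or MAUT specification is drop-in.  The
packaged EQ-5D-5L table is the published US tariff (worst state -0.573);
the packaged PROPr specification is a synthetic stand-in whose curves and
weights are plausible but not the published estimates — it is anchored
exactly to the published score range (-0.022 to 0.954).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, fields
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import ConfigurationError, ValidationError

EQ5D_ITEMS = (
    "mobility",
    "self_care",
    "usual_activities",
    "pain_discomfort",
    "anxiety_depression",
)
#: canonical CSV column names for the five items, in instrument order
EQ5D_COLUMNS = ("eq5d_mo", "eq5d_sc", "eq5d_ua", "eq5d_pd", "eq5d_ad")

PROPR_DOMAINS = (
    "physical_function",
    "pain_interference",
    "depression",
    "fatigue",
    "social_roles",
    "sleep_disturbance",
    "cognitive_function",
)


@dataclass(frozen=True)
class HealthState5L:
    """One respondent's five EQ-5D-5L item levels (1 = none ... 5 = extreme)."""

    mobility: int
    self_care: int
    usual_activities: int
    pain_discomfort: int
    anxiety_depression: int

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not (isinstance(v, (int, np.integer)) and 1 <= v <= 5):
                raise ValidationError(f"{f.name} level must be an integer in 1..5, got {v!r}")

    @property
    def levels(self) -> tuple[int, ...]:
        return tuple(getattr(self, f.name) for f in fields(self))


@dataclass(frozen=True)
class PromisProfile:
    """Seven PROPr domain scores on the standardized (theta) metric.

    Units are SDs of the reference population.  Higher is better for
    physical function, social roles and cognitive function; higher is worse
    for the four symptom domains.
    """

    physical_function: float
    pain_interference: float
    depression: float
    fatigue: float
    social_roles: float
    sleep_disturbance: float
    cognitive_function: float

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if v is None or not np.isfinite(v):
                raise ValidationError(f"domain {f.name} must be finite, got {v!r}")

    def as_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}


@dataclass(frozen=True)
class ValueSetTable:
    """Additive tariff: per item/level decrements from a full-health anchor."""

    instrument: str
    anchor: float
    minimum: float
    maximum: float
    decrements: Mapping[tuple[str, int], float]
    items: tuple[str, ...] = EQ5D_ITEMS

    def __post_init__(self):
        for item in self.items:
            for level in range(1, 6):
                if (item, level) not in self.decrements:
                    raise ConfigurationError(f"value set missing entry for ({item}, level {level})")
            if self.decrements[(item, 1)] != 0.0:
                raise ConfigurationError(f"level-1 decrement for {item} must be 0")
        worst = self.anchor - sum(max(self.decrements[(i, l)] for l in range(1, 6)) for i in self.items)
        best = self.anchor - sum(min(self.decrements[(i, l)] for l in range(1, 6)) for i in self.items)
        if worst < self.minimum - 1e-9 or best > self.maximum + 1e-9:
            raise ConfigurationError(
                f"achievable scores [{worst:.3f}, {best:.3f}] exceed declared "
                f"range [{self.minimum}, {self.maximum}]"
            )


@dataclass(frozen=True)
class MautSpec:
    """Multiplicative MAUT scoring specification for a domain-profile instrument.

    Disutility curves are tabulated monotone knots with linear interpolation;
    scores beyond the outer knots are clipped to them.  ``scale_constant`` is
    the multiplicative-MAUT C solving prod(1 + C*c_j) = 1 + C; the affine map
    onto the utility scale is utility = maximum - (maximum - minimum) * u.
    """

    instrument: str
    minimum: float
    maximum: float
    weights: Mapping[str, float]
    curves: Mapping[str, tuple[tuple[float, ...], tuple[float, ...]]]
    scale_constant: float
    domains: tuple[str, ...] = PROPR_DOMAINS

    def __post_init__(self):
        for d in self.domains:
            if d not in self.weights or d not in self.curves:
                raise ConfigurationError(f"MAUT spec missing domain {d}")
            knots, dis = self.curves[d]
            if len(knots) != len(dis) or len(knots) < 2:
                raise ConfigurationError(f"curve for {d} needs >= 2 aligned knots")
            if any(np.diff(knots) <= 0):
                raise ConfigurationError(f"curve knots for {d} must be strictly increasing")
            if min(dis) != 0.0 or max(dis) != 1.0:
                raise ConfigurationError(f"curve for {d} must span disutility [0, 1]")
            diffs = np.diff(dis)
            if not ((diffs >= 0).all() or (diffs <= 0).all()):
                raise ConfigurationError(f"curve for {d} must be monotone")

    def best_profile(self) -> PromisProfile:
        """Profile attaining zero disutility in every domain."""
        return PromisProfile(**{d: self._extreme(d, best=True) for d in self.domains})

    def worst_profile(self) -> PromisProfile:
        return PromisProfile(**{d: self._extreme(d, best=False) for d in self.domains})

    def _extreme(self, domain: str, best: bool) -> float:
        knots, dis = self.curves[domain]
        idx = int(np.argmin(dis)) if best else int(np.argmax(dis))
        return float(knots[idx])

    def domain_disutility(self, domain: str, score) -> np.ndarray:
        knots, dis = self.curves[domain]
        return np.interp(np.asarray(score, dtype=float), knots, dis)


def solve_maut_scale_constant(weights: Mapping[str, float]) -> float:
    """Solve prod_j(1 + C*c_j) = 1 + C for the multiplicative scaling constant C.

    For weights summing above 1 the root lies in (-1, 0); for weights summing
    below 1 it lies in (0, inf).  Weights summing to exactly 1 give the
    additive special case C -> 0.
    """
    c = np.array(list(weights.values()), dtype=float)
    if np.any(c <= 0):
        raise ConfigurationError("MAUT weights must be positive")
    total = c.sum()
    if abs(total - 1.0) < 1e-12:
        return 0.0

    def f(C):
        return np.prod(1.0 + C * c) - (1.0 + C)

    if total > 1:
        return brentq(f, -1.0 + 1e-12, -1e-12)
    return brentq(f, 1e-12, 1e9)


def score_eq5d(state, table: ValueSetTable | None = None) -> float:
    """Utility for one EQ-5D-5L health state: anchor minus the five decrements.

    ``state`` may be a :class:`HealthState5L` or a 5-sequence of levels in
    instrument order.
    """
    if table is None:
        table = us_eq5d5l_table()
    if not isinstance(state, HealthState5L):
        state = HealthState5L(*(int(v) for v in state))
    u = table.anchor - sum(table.decrements[(item, lvl)] for item, lvl in zip(table.items, state.levels))
    return float(u)


def _aggregate_disutility(spec: MautSpec, per_domain: np.ndarray) -> np.ndarray:
    """Combine per-domain disutilities (columns in spec.domains order)."""
    C = spec.scale_constant
    w = np.array([spec.weights[d] for d in spec.domains])
    if C == 0.0:
        return per_domain @ w
    return (np.prod(1.0 + C * w * per_domain, axis=-1) - 1.0) / C


def score_propr(profile, spec: MautSpec | None = None) -> float:
    """PROPr-style utility for one domain profile via the multiplicative MAUT."""
    if spec is None:
        spec = propr_maut_spec()
    if isinstance(profile, PromisProfile):
        vals = profile.as_dict()
    else:
        vals = dict(profile)
        missing = [d for d in spec.domains if d not in vals or vals[d] is None or not np.isfinite(vals[d])]
        if missing:
            raise ValidationError(f"profile missing/invalid domains: {', '.join(missing)}")
    per_domain = np.array([[spec.domain_disutility(d, vals[d]) for d in spec.domains]])
    u = _aggregate_disutility(spec, per_domain)[0]
    return float(spec.maximum - (spec.maximum - spec.minimum) * u)


def _parse_header(lines):
    meta = {}
    for ln in lines:
        if not ln.startswith("#"):
            break
        body = ln[1:].strip()
        if ":" in body:
            key, _, val = body.partition(":")
            meta[key.strip()] = val.strip()
    return meta


def load_value_set(path) -> ValueSetTable | MautSpec:
    """Read a scoring specification from a delimited text file.

    Additive tariffs carry columns (item, level, decrement); MAUT specs carry
    (domain, knot_score, disutility) plus ``# weight.<domain>:`` constants.
    Header ``# key: value`` lines declare instrument, kind, anchor and range.
    Round-trips unchanged through :func:`write_value_set`.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"value-set file not found: {path}")
    lines = path.read_text().splitlines()
    meta = _parse_header(lines)
    kind = meta.get("kind")
    if kind not in {"additive", "maut"}:
        raise ConfigurationError(f"{path}: header field 'kind' must be 'additive' or 'maut', got {kind!r}")
    try:
        body = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ConfigurationError(f"{path}: unreadable table: {exc}") from exc

    if kind == "additive":
        required = {"item", "level", "decrement"}
        if not required.issubset(body.columns):
            raise ConfigurationError(f"{path}: additive table needs columns {sorted(required)}")
        for key in ("anchor", "minimum", "maximum"):
            if key not in meta:
                raise ConfigurationError(f"{path}: missing header field '{key}'")
        dec = {(str(r.item), int(r.level)): float(r.decrement) for r in body.itertuples()}
        return ValueSetTable(
            instrument=meta.get("instrument", path.stem),
            anchor=float(meta["anchor"]),
            minimum=float(meta["minimum"]),
            maximum=float(meta["maximum"]),
            decrements=dec,
        )

    required = {"domain", "knot_score", "disutility"}
    if not required.issubset(body.columns):
        raise ConfigurationError(f"{path}: MAUT table needs columns {sorted(required)}")
    for key in ("minimum", "maximum"):
        if key not in meta:
            raise ConfigurationError(f"{path}: missing header field '{key}'")
    weights = {
        k.split(".", 1)[1]: float(v) for k, v in meta.items() if k.startswith("weight.")
    }
    if not weights:
        raise ConfigurationError(f"{path}: MAUT spec declares no 'weight.<domain>' constants")
    curves = {}
    for domain, grp in body.groupby("domain", sort=False):
        grp = grp.sort_values("knot_score")
        curves[str(domain)] = (
            tuple(grp["knot_score"].astype(float)),
            tuple(grp["disutility"].astype(float)),
        )
    return MautSpec(
        instrument=meta.get("instrument", path.stem),
        minimum=float(meta["minimum"]),
        maximum=float(meta["maximum"]),
        weights=weights,
        curves=curves,
        scale_constant=solve_maut_scale_constant(weights),
        domains=tuple(curves),
    )


def write_value_set(spec: ValueSetTable | MautSpec, path) -> None:
    """Serialize a scoring specification back to the text format."""
    path = Path(path)
    lines = [f"# instrument: {spec.instrument}"]
    if isinstance(spec, ValueSetTable):
        lines += [
            "# kind: additive",
            f"# anchor: {spec.anchor}",
            f"# minimum: {spec.minimum}",
            f"# maximum: {spec.maximum}",
            "item\tlevel\tdecrement",
        ]
        for item in spec.items:
            for level in range(1, 6):
                lines.append(f"{item}\t{level}\t{spec.decrements[(item, level)]}")
    else:
        lines += ["# kind: maut", f"# minimum: {spec.minimum}", f"# maximum: {spec.maximum}"]
        lines += [f"# weight.{d}: {spec.weights[d]}" for d in spec.domains]
        lines.append("domain\tknot_score\tdisutility")
        for d in spec.domains:
            knots, dis = spec.curves[d]
            lines += [f"{d}\t{k}\t{u}" for k, u in zip(knots, dis)]
    path.write_text("\n".join(lines) + "\n")


def _packaged(name: str) -> Path:
    return Path(resources.files("prefscore") / "data" / name)


@functools.lru_cache(maxsize=None)
def us_eq5d5l_table() -> ValueSetTable:
    """The packaged US EQ-5D-5L tariff (range -0.573 to 1)."""
    return load_value_set(_packaged("eq5d5l_us.tsv"))


@functools.lru_cache(maxsize=None)
def propr_maut_spec() -> MautSpec:
    """Packaged PROPr MAUT specification (synthetic stand-in, range -0.022 to 0.954)."""
    return load_value_set(_packaged("propr_maut_synthetic.tsv"))


class EQ5DScorer(TransformerMixin, BaseEstimator):
    """Stateless transformer: five EQ-5D-5L level columns -> utility vector.

    Accepts a DataFrame with the canonical ``eq5d_*`` columns (or an (n, 5)
    array of levels in instrument order) and returns an (n,) float array.
    """

    def __init__(self, table: ValueSetTable | None = None):
        self.table = table

    def fit(self, X, y=None):
        self._resolved_table_ = self.table or us_eq5d5l_table()
        return self

    def transform(self, X) -> np.ndarray:
        table = getattr(self, "_resolved_table_", None) or self.table or us_eq5d5l_table()
        if isinstance(X, pd.DataFrame):
            missing = [c for c in EQ5D_COLUMNS if c not in X.columns]
            if missing:
                raise ValidationError(f"missing EQ-5D-5L columns: {', '.join(missing)}")
            levels = X.loc[:, list(EQ5D_COLUMNS)].to_numpy()
        else:
            levels = np.asarray(X)
            if levels.ndim != 2 or levels.shape[1] != 5:
                raise ValidationError("expected an (n, 5) array of item levels")
        out = np.full(len(levels), np.nan)
        complete = ~np.isnan(levels.astype(float)).any(axis=1)
        for i in np.flatnonzero(complete):
            out[i] = score_eq5d(levels[i].astype(int), table)
        return out


class PROPrScorer(TransformerMixin, BaseEstimator):
    """Stateless transformer: seven PROMIS domain columns -> PROPr utility vector."""

    def __init__(self, spec: MautSpec | None = None):
        self.spec = spec

    def fit(self, X, y=None):
        self._resolved_spec_ = self.spec or propr_maut_spec()
        return self

    def transform(self, X) -> np.ndarray:
        spec = getattr(self, "_resolved_spec_", None) or self.spec or propr_maut_spec()
        if isinstance(X, pd.DataFrame):
            missing = [d for d in spec.domains if d not in X.columns]
            if missing:
                raise ValidationError(f"missing PROMIS domain columns: {', '.join(missing)}")
            scores = X.loc[:, list(spec.domains)].to_numpy(dtype=float)
        else:
            scores = np.asarray(X, dtype=float)
            if scores.ndim != 2 or scores.shape[1] != len(spec.domains):
                raise ValidationError(f"expected an (n, {len(spec.domains)}) array of domain scores")
        per_domain = np.column_stack(
            [spec.domain_disutility(d, scores[:, j]) for j, d in enumerate(spec.domains)]
        )
        u = _aggregate_disutility(spec, per_domain)
        out = spec.maximum - (spec.maximum - spec.minimum) * u
        out[np.isnan(scores).any(axis=1)] = np.nan
        return out


def score_dataframe(
    df: pd.DataFrame,
    table: ValueSetTable | None = None,
    spec: MautSpec | None = None,
) -> pd.DataFrame:
    """Append ``eq5d_utility`` / ``propr_utility`` columns where inputs exist."""
    out = df.copy()
    if set(EQ5D_COLUMNS).issubset(df.columns):
        out["eq5d_utility"] = EQ5DScorer(table).fit(df).transform(df)
    domains = (spec or propr_maut_spec()).domains
    if set(domains).issubset(df.columns):
        out["propr_utility"] = PROPrScorer(spec).fit(df).transform(df)
    return out
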