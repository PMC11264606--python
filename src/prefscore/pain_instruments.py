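"""Scoring rules for the back-pain impact instruments and the chronic-pain flag.

All scorers are vectorized: pass a 1-d sequence of one respondent's items
or a 2-d array / DataFrame slice (rows = respondents, columns = items).
Higher scores mean worse pain or disability on every instrument.  Missing
items are not imputed: any missing item yields a missing (NaN) score.

Instruments
-----------
ODI        10 items scored 0-5, total rescaled to 0-100 (sum / 50 * 100).
RMDQ       sum of 24 dichotomous items, range 0-24.
PEG        mean of 3 items on 0-10 numeric rating scales, range 0-10.
STarT Back sum of 9 dichotomous items, range 0-9.
GCPS       3-item pain-intensity and 3-item disability subscores, each the
           item mean rescaled to 0-100 (mean x 10), following the
           instrument's published convention.
Chronic pain (task-force definition): pain persisting at least 3 months AND
present at least half the days of the past 6 months.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import ValidationError

#: canonical CSV column layouts
ODI_COLUMNS = tuple(f"odi_{i}" for i in range(1, 11))
RMDQ_COLUMNS = tuple(f"rmdq_{i}" for i in range(1, 25))
PEG_COLUMNS = tuple(f"peg_{i}" for i in range(1, 4))
STARTBACK_COLUMNS = tuple(f"sb_{i}" for i in range(1, 10))
GCPS_INTENSITY_COLUMNS = ("gcps_i1", "gcps_i2", "gcps_i3")
GCPS_DISABILITY_COLUMNS = ("gcps_d1", "gcps_d2", "gcps_d3")


def _as_items(items, n_items: int, lo: float, hi: float, name: str) -> np.ndarray:
    arr = np.asarray(items, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.ndim != 2 or arr.shape[1] != n_items:
        raise ValidationError(f"{name} expects {n_items} items per respondent, got shape {arr.shape}")
    finite = arr[np.isfinite(arr)]
    if finite.size and (finite.min() < lo or finite.max() > hi):
        raise ValidationError(f"{name} items must lie in [{lo}, {hi}]")
    return arr


def _squeeze(values: np.ndarray, was_1d: bool):
    return float(values[0]) if was_1d else values


def score_odi(items):
    """Oswestry Disability Index: 10 items 0-5, total rescaled to 0-100."""
    was_1d = np.asarray(items, dtype=float).ndim == 1
    arr = _as_items(items, 10, 0, 5, "ODI")
    return _squeeze(arr.sum(axis=1) / 50.0 * 100.0, was_1d)


def score_rmdq(items):
    """Roland-Morris Disability Questionnaire: sum of 24 dichotomous items (0-24)."""
    was_1d = np.asarray(items, dtype=float).ndim == 1
    arr = _as_items(items, 24, 0, 1, "RMDQ")
    return _squeeze(arr.sum(axis=1), was_1d)


def score_peg(items):
    """PEG: mean of the 3 pain intensity/interference items, range 0-10."""
    was_1d = np.asarray(items, dtype=float).ndim == 1
    arr = _as_items(items, 3, 0, 10, "PEG")
    return _squeeze(arr.mean(axis=1), was_1d)


def score_startback(items):
    """STarT Back screening tool: sum of 9 dichotomous items (0-9)."""
    was_1d = np.asarray(items, dtype=float).ndim == 1
    arr = _as_items(items, 9, 0, 1, "STarT Back")
    return _squeeze(arr.sum(axis=1), was_1d)


def score_gcps(intensity_items, disability_items):
    """Graded Chronic Pain Scale: (intensity, disability) subscores on 0-100.

    Each subscore is the mean of its three 0-10 items rescaled by x 10.
    """
    was_1d = np.asarray(intensity_items, dtype=float).ndim == 1
    ii = _as_items(intensity_items, 3, 0, 10, "GCPS intensity")
    dd = _as_items(disability_items, 3, 0, 10, "GCPS disability")
    if ii.shape[0] != dd.shape[0]:
        raise ValidationError("GCPS intensity and disability blocks must align")
    return _squeeze(ii.mean(axis=1) * 10.0, was_1d), _squeeze(dd.mean(axis=1) * 10.0, was_1d)


def classify_chronic_pain(duration_ge_3mo, pain_half_days_6mo):
    """Task-force chronic pain flag: both the duration and frequency criteria met.

    NaN in either flag propagates to a NaN classification.
    """
    d = np.asarray(duration_ge_3mo, dtype=float)
    f = np.asarray(pain_half_days_6mo, dtype=float)
    for name, arr in (("duration", d), ("frequency", f)):
        finite = arr[np.isfinite(arr)]
        if finite.size and not np.isin(finite, (0.0, 1.0)).all():
            raise ValidationError(f"{name} flag must be binary 0/1")
    out = np.where(np.isnan(d) | np.isnan(f), np.nan, ((d == 1) & (f == 1)).astype(float))
    return float(out) if out.ndim == 0 else out


def score_instruments(df: pd.DataFrame) -> pd.DataFrame:
    """Score every instrument whose canonical item columns are present.

    Returns a DataFrame of instrument scores aligned to ``df``'s index.
    """
    out = pd.DataFrame(index=df.index)
    if set(ODI_COLUMNS).issubset(df.columns):
        out["odi"] = score_odi(df[list(ODI_COLUMNS)].to_numpy())
    if set(RMDQ_COLUMNS).issubset(df.columns):
        out["rmdq"] = score_rmdq(df[list(RMDQ_COLUMNS)].to_numpy())
    if set(PEG_COLUMNS).issubset(df.columns):
        out["peg"] = score_peg(df[list(PEG_COLUMNS)].to_numpy())
    if set(STARTBACK_COLUMNS).issubset(df.columns):
        out["startback"] = score_startback(df[list(STARTBACK_COLUMNS)].to_numpy())
    if set(GCPS_INTENSITY_COLUMNS).issubset(df.columns) and set(GCPS_DISABILITY_COLUMNS).issubset(df.columns):
        i, d = score_gcps(
            df[list(GCPS_INTENSITY_COLUMNS)].to_numpy(), df[list(GCPS_DISABILITY_COLUMNS)].to_numpy()
        )
        out["gcps_intensity"] = i
        out["gcps_disability"] = d
    if {"pain_duration_ge_3mo", "pain_half_days_6mo"}.issubset(df.columns):
        out["chronic_back_pain"] = classify_chronic_pain(
            df["pain_duration_ge_3mo"].to_numpy(), df["pain_half_days_6mo"].to_numpy()
        )
    return out
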