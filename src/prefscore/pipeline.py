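"""End-to-end study pipeline: one cohort table in, one structured report out.

Mirrors the published analysis ordering: baseline agreement between the
two utilities, correlations with the pain-impact measures, the 22-condition
regressions and their coefficient-vector comparison, the bidirectional
crosswalk (OLS and beta-family), and the longitudinal change block.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import agreement, condition_models, crosswalk
from .exceptions import FitFailureError, SchemaError
from .synthetic import RETRO_ITEMS

log = logging.getLogger("prefscore")

_REQUIRED_BASELINE = ("person_id", "eq5d_utility", "propr_utility")
_PAIN_COLUMNS = ("odi", "rmdq", "peg", "startback", "gcps_intensity", "gcps_disability", "chronic_back_pain")


@dataclass
class StudyConfig:
    """Options governing one pipeline run."""

    fit_beta_models: bool = True
    beta_mode: str = "beta"
    conditions: tuple = condition_models.CONDITIONS
    retrospective_items: tuple = RETRO_ITEMS
    seed: int | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d or {})
        for key in ("conditions", "retrospective_items"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class StudyReport:
    """Structured results; every block carries its n and provenance tag."""

    provenance: dict
    agreement: dict
    pain_correlations: dict | None
    condition_fits: dict | None
    crosswalks: dict
    longitudinal: dict | None
    blocks_absent: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "agreement": self.agreement,
            "pain_correlations": self.pain_correlations,
            "condition_fits": self.condition_fits,
            "crosswalks": self.crosswalks,
            "longitudinal": self.longitudinal,
            "blocks_absent": self.blocks_absent,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, default=_jsonify)

    def to_text(self) -> str:
        a = self.agreement
        lines = [
            "Study report",
            "============",
            f"baseline n = {a['n']}",
            "",
            "Baseline agreement (EQ-5D-5L vs PROPr)",
            f"  mean (SD): {a['mean_x']:.3f} ({a['sd_x']:.3f}) vs {a['mean_y']:.3f} ({a['sd_y']:.3f})",
            f"  mean difference: {a['mean_difference']:.3f}",
            f"  Pearson r: {a['pearson_r']:.2f}",
            f"  ICC consistency (two-way mixed): {a['icc_mixed']:.2f}",
            f"  ICC absolute agreement (two-way random): {a['icc_random']:.2f}",
            f"  EQ-5D-5L ceiling fraction: {a['ceiling_fraction']:.2f}",
        ]
        if self.condition_fits:
            lines += [
                "",
                "22-condition regressions",
                f"  adj R2: propr {self.condition_fits['propr']['adj_r2']:.2f}, "
                f"eq5d {self.condition_fits['eq5d']['adj_r2']:.2f}",
                f"  coefficient-vector correlation: {self.condition_fits['coefficient_correlation']:.2f}",
            ]
        for direction, block in self.crosswalks.items():
            ev = block["ols_evaluation"]
            lines += [
                "",
                f"Crosswalk {direction}: intercept {block['model']['intercept']:.3f}, "
                f"slope {block['model']['slope']:.3f}",
                f"  adj R2 {ev['adj_r2']:.2f}, r {ev['pearson_r']:.2f}, "
                f"ICC {ev['icc_random']:.2f}, NMAE {ev['nmae']:.2f}",
            ]
        if self.longitudinal:
            lines += [
                "",
                "Six-month change (back-pain subset)",
                f"  n = {self.longitudinal['n']}",
                f"  change-change r: {self.longitudinal['change_change_r']:.2f}",
            ]
        if self.blocks_absent:
            lines += ["", f"absent blocks: {', '.join(self.blocks_absent)}"]
        return "\n".join(lines)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="index")
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _validate_schema(table: pd.DataFrame, required, label: str) -> None:
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise SchemaError(missing, f"{label} table missing columns: {', '.join(sorted(missing))}")


def run_study(
    baseline: pd.DataFrame,
    followup: pd.DataFrame | None = None,
    config: StudyConfig | dict | None = None,
) -> StudyReport:
    """Run the full comparison pipeline on a cohort table.

    Deterministic given its inputs; all statistics are delegated to the
    component modules.  Missing optional blocks (pain instruments absent,
    no follow-up) are marked absent rather than failing.
    """
    if not isinstance(config, StudyConfig):
        config = StudyConfig.from_dict(config)
    _validate_schema(baseline, _REQUIRED_BASELINE, "baseline")
    log.info("baseline rows: %d", len(baseline))
    absent = []

    eq = baseline["eq5d_utility"].to_numpy(dtype=float)
    pr = baseline["propr_utility"].to_numpy(dtype=float)
    rep = agreement.agreement_report(eq, pr)
    agreement_block = rep.to_dict()
    agreement_block["ceiling_fraction"] = float(np.mean(eq[np.isfinite(eq)] == np.nanmax(eq)))
    log.info("agreement block complete (n=%d)", rep.n)

    pain_block = None
    present_pain = [c for c in _PAIN_COLUMNS if c in baseline.columns]
    if present_pain:
        sub = baseline.loc[baseline.get("back_pain_flag", 1) == 1] if "back_pain_flag" in baseline.columns else baseline
        r, p, n = agreement.correlation_matrix(sub, ["propr_utility", "eq5d_utility", *present_pain])
        pain_block = {
            "n": int(len(sub)),
            "r": r.loc[present_pain, ["propr_utility", "eq5d_utility"]],
            "p": p.loc[present_pain, ["propr_utility", "eq5d_utility"]],
        }
    else:
        absent.append("pain_correlations")

    condition_block = None
    if set(config.conditions).issubset(baseline.columns):
        fits = {}
        for label, outcome in (("propr", "propr_utility"), ("eq5d", "eq5d_utility")):
            fit = condition_models.fit_condition_regression(baseline, outcome, config.conditions)
            fits[label] = fit
        condition_block = {k: f.to_dict() for k, f in fits.items()}
        condition_block["coefficient_correlation"] = condition_models.compare_coefficient_vectors(
            fits["propr"], fits["eq5d"]
        )
        log.info("condition regressions complete (n=%d)", fits["propr"].n)
    else:
        absent.append("condition_fits")

    crosswalk_block = {}
    for direction, src, tgt in (
        (crosswalk.PROPR_TO_EQ5D, pr, eq),
        (crosswalk.EQ5D_TO_PROPR, eq, pr),
    ):
        model = crosswalk.fit_ols_map(src, tgt, direction=direction)
        block = {
            "model": json.loads(model.to_json()),
            "ols_evaluation": crosswalk.evaluate_map(model, src, tgt).to_dict(),
        }
        if config.fit_beta_models:
            try:
                beta = crosswalk.fit_beta_binomial_map(src, tgt, mode=config.beta_mode)
                keep = np.isfinite(src) & np.isfinite(tgt)
                block["beta_evaluation"] = crosswalk.evaluate_predictions(
                    tgt[keep], beta.predict(src[keep]), n_params=3
                ).to_dict()
                block["beta_params"] = beta.params_
            except FitFailureError as exc:
                block["beta_evaluation"] = None
                block["beta_error"] = str(exc)
        crosswalk_block[direction] = block
    log.info("crosswalk block complete")

    longitudinal = None
    if followup is not None and len(followup):
        retro = [c for c in config.retrospective_items if c in followup.columns]
        cc = condition_models.change_correlations(baseline, followup, retro)
        longitudinal = {
            "n": cc["n"],
            "change_change_r": cc["change_change_r"],
            "change_change_p": cc["change_change_p"],
            "items": cc["items"],
        }
        log.info("longitudinal block complete (n=%d)", cc["n"])
    else:
        absent.append("longitudinal")

    provenance = {
        "n_baseline": int(len(baseline)),
        "n_followup": int(len(followup)) if followup is not None else 0,
        "seed": config.seed,
    }
    return StudyReport(
        provenance=provenance,
        agreement=agreement_block,
        pain_correlations=pain_block,
        condition_fits=condition_block,
        crosswalks=crosswalk_block,
        longitudinal=longitudinal,
        blocks_absent=absent,
    )
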