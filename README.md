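# prefscore

Tools for comparing two preference-based health-utility measures — the
EQ-5D-5L index and the PROMIS-based PROPr score — on the common QALY scale
(0 = dead, 1 = full health).  The package is aimed at outcomes researchers
and health economists who need to (a) score the instruments from item-level
survey data, (b) quantify how well the two utilities agree, (c) map one
score onto the other for meta-analysis and cost-effectiveness work, and
(d) test such pipelines without access to restricted survey data.

## What it computes

**Scoring.** EQ-5D-5L health states (five items, levels 1–5) are scored
additively against a value-set tariff, `U = 1 − Σ d(item, level)`; the
packaged US tariff spans −0.573 to 1.  PROPr-style profiles (seven PROMIS
domain scores on the standardized theta metric) are scored with a
multiplicative multi-attribute utility function,

    1 + C·u = Π_j (1 + C·c_j·u_j(θ_j)),

where `u_j` are per-domain disutilities, `c_j` domain weights, and `C`
solves `Π (1 + C·c_j) = 1 + C`; the aggregate disutility is mapped affinely
onto the published −0.022 to 0.954 range.  Both engines read plain-text
value-set files, so alternative tariffs are drop-in.

**Agreement.** Pearson *r*, the two-way mixed-effects (consistency) ICC
`(MS_between − MS_within)/(MS_between + MS_within)` and the two-way
random-effects (absolute agreement) ICC, which additionally penalizes the
mean difference between the measures; the normalized mean absolute error
`NMAE = mean|obs − pred| / SD(obs)`; and the Cohen effect-size conversion
`r = d/√(d² + 4)`.

**Crosswalk.** OLS regression of one utility on the other, followed by
linear equating — predicted scores are rescaled to the observed target
mean/SD, undoing regression-to-the-mean shrinkage — and clamping to the
instrument range, always in the order predict → equate → clamp.  The
published US general-population constants are packaged
(`published_model`), e.g. `EQ5D = 0.563 + 0.543·PROPr`.  A beta-regression
alternative on the unit interval (continuous logit-link likelihood, or a
true beta-binomial with integer trials) is available for comparison.

**Condition regressions.** Each utility regressed simultaneously on 22
binary health-condition indicators, with zero-order correlations,
significance stars and a product-moment comparison of the two 22-element
coefficient vectors.

**Synthetic cohorts.** A generator calibrated so that the simulated
baseline reproduces the published summary structure — utility means/SDs
(0.855/0.195 and 0.539/0.249), their correlation (0.69), the 31 %
EQ-5D-5L ceiling, condition prevalences and effects — plus a back-pain
follow-up wave with mean-zero six-month change, change-score correlation
0.34, and ordinal retrospective-change items.  See `docs/methods.md` for
the generating model and its limitations.

## Worked example

```python
from prefscore import CohortSpec, generate_baseline, generate_followup, run_study

spec = CohortSpec()                               # published study conditions
baseline = generate_baseline(spec, seed=0)        # n = 4,098
followup = generate_followup(baseline, spec, seed=1)  # n = 1,256 back-pain subset
print(run_study(baseline, followup).to_text())
```

prints

```
Study report
============
baseline n = 4098

Baseline agreement (EQ-5D-5L vs PROPr)
  mean (SD): 0.854 (0.196) vs 0.535 (0.251)
  mean difference: 0.318
  Pearson r: 0.70
  ICC consistency (two-way mixed): 0.68
  ICC absolute agreement (two-way random): 0.34
  EQ-5D-5L ceiling fraction: 0.31

22-condition regressions
  adj R2: propr 0.13, eq5d 0.03
  coefficient-vector correlation: 0.79

Crosswalk propr_to_eq5d: intercept 0.562, slope 0.544
  adj R2 0.49, r 0.73, ICC 0.71, NMAE 0.49

Crosswalk eq5d_to_propr: intercept -0.227, slope 0.893
  adj R2 0.49, r 0.71, ICC 0.71, NMAE 0.58

Six-month change (back-pain subset)
  n = 1256
  change-change r: 0.36
```

Reading the numbers: the two utilities correlate strongly (r = 0.70) and
agree well up to a constant shift (consistency ICC 0.68), but the 0.32
mean difference collapses absolute agreement to 0.34 — the central
phenomenon this package quantifies.  The fitted crosswalk slopes (0.544,
0.893) recover the packaged published constants because the cohort is
calibrated to the same moments.  The condition-regression R² values are
deliberately *not* comparable to real survey data (see `docs/methods.md`).

The same pipeline is scriptable from the shell:

```bash
prefscore simulate --n 4098 --seed 0 --out-dir cohort/
prefscore run-study --baseline cohort/baseline.csv --followup cohort/followup.csv --out report/
prefscore crosswalk --direction propr2eq5d --published --input scores.csv --output mapped.csv
```

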