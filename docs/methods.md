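# Methods

This note documents the statistical models behind `prefscore`, the choices
made where the design was genuinely open, and what the synthetic cohorts do
and do not establish about real survey data.

## Utility scoring

**EQ-5D-5L.** The index is additive: a full-health anchor (1.0) minus one
tariff decrement per item/level, with level-1 decrements fixed at zero.
The packaged file `data/eq5d5l_us.tsv` carries the published US time
trade-off tariff; its worst state (55555) scores −0.573 and the engine
verifies at load time that all 3,125 achievable scores respect the declared
range.  Any tariff in the same three-column text format is drop-in.

**PROPr.** The engine implements the multiplicative multi-attribute
utility form: per-domain disutilities `u_j(θ_j) ∈ [0, 1]` (tabulated
monotone curves, linear interpolation between knots, clipped beyond the
outer knots), domain weights `c_j`, and the scaling constant `C` solving
`Π_j (1 + C·c_j) = 1 + C`.  Aggregate disutility is mapped affinely onto
the instrument range so the all-best profile scores exactly 0.954 and the
all-worst exactly −0.022.  The packaged curve file
`data/propr_maut_synthetic.tsv` is a **synthetic stand-in**: the weights
and curve shapes are plausible but are not the published estimation, which
is not reproducible from publicly printed numbers alone; only the anchors
and the functional form are faithful.  Analyses that depend on exact PROPr
values for real respondents must substitute the published scoring tables
in the same file format.  Domain scores are taken as given (theta metric,
SD units); IRT estimation from raw items is out of scope.

## Agreement statistics

Both ICCs come from the two-way person × measure ANOVA with k = 2
measures.  Single-measure forms are used throughout:

* consistency (two-way mixed):
  `ICC(C,1) = (MS_between − MS_within) / (MS_between + (k−1)·MS_within)`
* absolute agreement (two-way random):
  `ICC(A,1) = (MS_between − MS_within) /
   (MS_between + (k−1)·MS_within + k·(MS_time − MS_within)/n)`

The absolute-agreement form penalizes the between-measure mean difference
through `MS_time`; its large-n limit is the concordance correlation
`2·r·s₁·s₂/(s₁² + s₂² + (m₁−m₂)²)`, which the package exposes as a
closed-form cross-check and the tests verify against both a brute-force
ANOVA oracle and pingouin.  With the baseline moments (means 0.855/0.539,
SDs 0.195/0.249, r = 0.69) these forms give 0.670 and 0.335.

Sample SDs use the n−1 denominator; all pairwise statistics are
complete-case; p-values are two-sided from the t distribution with no
multiplicity adjustment.  NMAE divides the mean absolute deviation by the
SD of the *observed* vector, making it scale-invariant.

## Crosswalk

The mapping pipeline is strictly predict → equate → clamp:

1. `ŷ = a + b·x` (OLS);
2. `y_eq = m_t + (s_t/s_p)·(ŷ − m_t)` where `(m_t, s_t)` are the observed
   target mean/SD and `s_p` the SD of the predictions — linear equating
   restores the attenuated spread (OLS predictions have SD `|b|·s_x < s_t`
   whenever `|r| < 1`);
3. recode outside the clamp bounds to the nearest bound.

Applied to its own fitting sample, the pre-clamp equated scores carry the
target mean and SD exactly; the tests assert this to 1e-10 relative.  The
packaged published models use the printed constants at 3-decimal precision
(including the published equating target mean 0.538 for PROPr, which
differs in the last digit from the descriptive baseline mean 0.539 printed
elsewhere; the equating equation's value is used).  Age/gender covariates
are supported in principle but off by default — in the source analysis they
added only one adjusted-R² point.

**Beta-family alternative.** Because beta-type likelihoods need a 0–1
outcome, the target is rescaled by `(y − min)/range` with the transform
stored for inversion.  The published analysis names a beta-binomial model
but not its trials denominator, so both readings are implemented: a
continuous beta regression (logit mean link, precision φ, boundary values
nudged by `(u(n−1)+0.5)/n`) and a true beta-binomial with configurable
integer trials (default 100).  The two give closely similar slopes on
continuous utility data; the continuous mode is the default.  The
unit-interval transform may also be fixed to a theoretical range rather
than estimated, which is what keeps the parameters identified in the
simulation-based recovery tests.

## Condition regressions

One OLS model per outcome with all 22 binary indicators entered
simultaneously, no selection or shrinkage.  Zero-order correlations are
reported alongside coefficients so suppression effects (coefficient sign
opposing the marginal association) are visible.  Rank-deficiency is
detected before fitting and the error names the offending columns.

## Synthetic cohort generator

The generator is explicitly a stand-in for restricted survey data.  It is
calibrated to published *summary* structure, not to the full shape of real
utility distributions.

**Baseline model.**

* 22 condition indicators drawn independently at the published prevalences
  (real conditions co-occur; an independence assumption is the minimal
  choice given only marginal prevalences).  Two all-zero fake-condition
  screening columns are included for schema fidelity.
* Latent utilities are linear in the conditions, using the packaged
  coefficient table as true effects, plus correlated Gaussian noise.
* Observed PROPr clamps its latent to [−0.022, 0.954].
* Observed EQ-5D-5L uses a latent-threshold ceiling: latents at or above a
  threshold `c` map to exactly 1; the rest are capped at the second-best
  observable utility (0.94, roughly the best non-11111 US tariff state)
  and floored at −0.573.  A plain right-censored Gaussian is
  over-determined here — matching mean 0.855 and SD 0.195 under censoring
  at 1 forces a 45 % ceiling — so the threshold is a third free parameter;
  the solved default is latent N(1.04, 0.37) with c ≈ 1.23.  The model
  implies a pile-up at 0.94 (≈30 %), a stylized stand-in for the real
  clustering of near-full-health states.

**Calibration** (`calibrate`, cached per spec) solves, in order: the
EQ-5D-5L latent (mean, SD, threshold) against the mean/SD/ceiling targets
by root-finding on dense-grid quadrature moments; the PROPr latent
(mean, SD) likewise; the latent correlation against the observed-scale
correlation target via a semi-analytic integral (the PROPr clamp is
integrated out in closed form conditional on the EQ latent — ordinary
Gauss–Hermite quadrature fails here because the EQ transform is
discontinuous); and finally the noise SDs/correlation that reconcile the
latent totals with the condition-driven systematic parts.  Infeasible
targets (SD smaller than the systematic variance, unreachable
correlations) raise calibration errors with residuals.

**Follow-up model.** A back-pain subset (condition prevalence 0.38) is
sampled; latent changes are bivariate normal and pushed through the same
transforms.  Because censoring distorts observed changes, the change
drifts (to zero the observed mean change) and the latent change
correlation (to hit the observed 0.34) are solved by root-finding on a
fixed-seed internal Monte-Carlo (seed constant, independent of the user
seed, m = 300,000), so generation remains reproducible.  Change SDs
default to 0.13 (EQ-5D-5L) and 0.19 (PROPr), consistent with the scale of
published test-retest reliability (≈0.77) for such measures over months.
Nine ordinal retrospective-change items are generated from a standardized
composite of the two observed changes with thresholds placed to match the
published "About the same" fractions (58–76 %); the remaining mass splits
symmetrically between the worse/better sides with most of it adjacent to
"same" (the split is not published).  Item loadings are set analytically
from the target correlations with an ordinal-attenuation correction, so
achieved correlations land near (not exactly on) the 0.06–0.20 targets.

**Pain instruments.** For the back-pain subgroup, a shared latent severity
(negatively loaded on both utilities) drives ODI, RMDQ, PEG, STarT Back
and both GCPS subscores, discretized to each instrument's step size and
clipped to its range.  Marginal means/SDs (e.g. ODI 22 ± 16) are set to
community back-pain values; the loadings approximate the published
−0.55…−0.75 utility correlations after discretization loss.  The
chronic-pain flag is the conjunction of duration and frequency indicators
derived from the same severity.

**What passing tests do and do not show.** Matching moments, ceiling and
correlations means statistics that are functions of those summaries (ICCs,
OLS slopes, equating constants, adjusted R² of the cross-measure
regression) reproduce the published values on synthetic data.  Statistics
that depend on the full distributional shape do **not** transfer and are
deliberately not asserted against published values: NMAE of the crosswalk,
the equated mean/SD after clamping, beta-model agreement indices, the
pain-instrument correlation table, and the condition-regression R²
(published ≈0.40; on synthetic data it equals the systematic variance
share, ≈0.14 for PROPr and ≈0.05 for EQ-5D-5L, because independent
conditions with the printed coefficients generate far less explained
variance than the co-occurring conditions of a real cohort).  These get
property-based checks instead: ANOVA-oracle equivalence, equating moment
preservation, clamp-bound respect, and simulation-based parameter
recovery.  Parameter recovery of condition effects is asserted on the
generator's latent utilities, where the linear model is exactly true; the
censoring transform attenuates observed-scale coefficients by design.

## Numerical choices

* Dense-grid trapezoid quadrature (8,193 points over ±8.5 SD) for censored
  moments; closed-form clipped-normal means where available; `brentq` /
  `fsolve` with residual tolerances of 1e-8 on calibration targets.
* The exact-moment bivariate sampler whitens a Gaussian draw against its
  own sample covariance and recolours to the targets, so moment-determined
  statistics are reproducible to machine precision regardless of seed.
* Utilities are carried at full floating precision; rounding to the
  3-decimal published convention happens only in reports.
* Ties at clamp bounds are genuine point masses, intended (the ceiling
  fraction is literally `mean(u == 1)`).
* Simulation sizes in tests (10⁴–10⁵ cross-sectional, 3–5 × 10⁴
  longitudinal) keep Monte-Carlo error a factor of a few below each
  assertion's tolerance.

## Known limitations

* The packaged PROPr curves are a synthetic stand-in (above); EQ-5D-5L
  value sets other than the US tariff must be supplied by the user.
* Real EQ-5D-5L/PROPr joint distributions are skewed and multi-modal;
  only moments, ceiling and correlation structure are emulated.
* Condition indicators are independent in the generator; a dependence
  structure would be needed to emulate published condition-model R².
* ICC confidence intervals, survey weighting, and Tobit/CLAD/mixture
  mapping models are out of scope.
* ODI scoring does not implement the canonical rescaling for skipped
  sections; any missing item yields a missing score.
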