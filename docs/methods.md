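# Methods notes

## Study design being emulated

`vo2val` operationalizes the external validation of VO₂max prediction
equations against directly measured CPET values in endurance athletes.
Validation is *calibration-centred*: rather than asking whether a model
discriminates between subjects, it asks whether predicted values agree with
observed values in level (calibration-in-the-large), in scale (calibration
slope), and in explained variance (adjusted R²) — separately within
subgroups defined by sex, test modality (treadmill vs cycle ergometer),
age band, and SD-banded endurance level.

## VO₂max definition

VO₂max is the highest 15-s average of the breath-by-breath VO₂ signal at
test end. Breaths are irregular, so `vo2max_15s` treats the series as a
piecewise-linear signal and maximizes the time-weighted mean over sliding
windows `[t, t + 15 s]`. Because the windowed mean of a piecewise-linear
signal attains its extrema when a window edge coincides with a breath
sample, only sample-aligned window starts (and ends) are evaluated, which
makes the reduction exact rather than grid-approximate. Fixed contiguous
15-s bins were the alternative reading; the sliding window was chosen
because it is invariant to the arbitrary phase of bin boundaries and never
reports a lower value than any binning would.

Stored records carry relative VO₂max (mL·min⁻¹·kg⁻¹) as the single source
of truth; absolute values (mL·min⁻¹, L·min⁻¹) are always derived via body
mass at the point of use, so the three units can never disagree on disk.

## Eligibility

Inclusion requires training ≥ 3 months, age ≥ 18 y, clean
medical/medication/smoker flags, all screened variables within ±3 SD, and
a passed maximal-exertion assessment (≥ 6 of 7 criteria, all inclusive at
the boundary: RER ≥ 1.10, VO₂ plateau with stage growth < 100 mL·min⁻¹,
fR ≥ 45 min⁻¹, Borg ≥ 18, lactate ≥ 8 mmol·L⁻¹, post-RCP intensity gain
≥ 10 %, peak HR ≥ predicted max − 15 bpm). Design points:

- **Predicted HRmax** defaults to 220 − age; the criterion references a
  predicted maximum without fixing a formula, so the predictor is an
  injectable function.
- **HR criterion direction.** "≥ 15 bpm below predicted max" is read as
  *within* 15 bpm of predicted max. The literal reading would reward low
  peak heart rates, contradicting the purpose of a maximal-effort criterion.
- **Outlier screen**: single pass, moments computed once on the input
  cohort, within sex, over {VO₂max, RER, lactate, fR, HR, height, mass,
  BMI}. Iterative re-screening would change n each pass and is not part of
  the emulated procedure; `apply_inclusion(run_outlier_screen=False)`
  makes a second filter pass idempotent.
- The screen runs before the effort filter; the order is configurable by
  calling the pieces directly.
- A missing effort field counts as an unmet criterion (flagged), not an
  error: assessment must be total over partially recorded tests.

## Stratification

Age is truncated to completed years, then bucketed 18–30 / 31–45 / 46–60 /
≥ 61. Endurance level is the z-score of the RCP variable — speed at the
respiratory compensation point for treadmill tests (km·h⁻¹), relative
power for cycle tests (W·kg⁻¹) — standardized **within sex × modality**.
Standardizing within sex alone is impossible here because speed and W·kg⁻¹
are incommensurable; the within-modality refinement is the package's
explicit choice. Band boundaries ±0.5 and ±1.5 belong to the transition
group, following the strict/weak inequality pattern of the rule
(HTEA: z > 1.5; REA: |z| < 0.5; LTEA: z < −1.5). Under a normal z these
bands imply ≈ 38.3 % recreational and ≈ 6.7 % low-trained athletes, which
the acceptance script re-derives by simulation. Subgroups with n ≥ 100
are flagged reliable, following common prediction-model validation
guidance on minimum external-validation sample size.

## Equation registry

Thirteen equations from eight publications, fixed metadata: Wilson
(male-only) and Fitzgerald (female-only) meta-analytic age regressions,
applicable to both modalities, in mL·min⁻¹·kg⁻¹; the two sex-specific
Wasserman/Hansen equations in mL·min⁻¹; three Kokkinos cycle-ergometry
equations (male / female / combined) in mL·min⁻¹·kg⁻¹; Mylius in mL·min⁻¹
(cycle); the FRIEND treadmill equation of Myers et al. in mL·min⁻¹·kg⁻¹;
Nevill's allometric and additive treadmill models in mL·min⁻¹·kg⁻¹; and
Petek's athlete-derived treadmill and cycle equations in L·min⁻¹.

Coefficient bodies live in one reviewable table in `registry.py`, each
with a citation string. Functional forms follow the cited publications;
users whose edition of a source differs can `register()` a replacement or
load linear models from a YAML/JSON coefficient file — the registry
contract (counts, applicability, units, evaluation purity) is what the
test suite pins, deliberately not the coefficient values, so corrected
transcriptions drop in without touching the engine. Out-of-range inputs
are not refused: equations are applied cohort-wide, as in validation
practice, and disagreement shows up in the calibration metrics.

Unit discipline: observed VO₂max is converted to each model's native
output unit before any comparison (`PredictionTable` carries the unit per
row); non-applicable sex/modality cells are flagged, never zero-filled.

## Calibration metrics

OLS of observed on predicted (statsmodels). C2 is the slope; C1 defaults
to the free intercept of that regression — on intercept-scale magnitudes —
with the mean(observed) − mean(predicted) convention available, and every
C1 is convention-tagged so the two can never be silently conflated.
Adjusted R² uses 1 − (1 − R²)(n − 1)/(n − 2) (one predictor) and can be
negative. RMSE divides by n (root of the mean squared residual of the
fit). The paired mean difference is predicted − observed (positive =
overestimation) with a t-based 95 % CI; with zero-variance differences the
t statistic is undefined and p is reported as 1.0 with a collapsed CI.
Significance of C2 is the slope's two-sided Wald test; of C1, the
intercept's Wald test (free-intercept) or the paired t (mean-difference).
No multiple-testing correction is applied by default. Degenerate cells
(n < 3 or constant predictions) are emitted with explicit error markers
rather than dropped, and the endurance-axis panels exclude the transition
group while whole-population panels keep it.

## Synthetic cohort generator

The generator emulates the joint structure the pipeline needs, not real
breath-by-breath physiology:

- Sex ~ Bernoulli(0.8476); modality per sex (treadmill probability
  3330/4459 male, 671/801 female).
- Age, height, mass, body fat: per-sex truncated normals. The underlying
  normal's location/scale are **moment-matched** so the truncated
  distribution has exactly the configured mean/SD (with age ≥ 18 the naive
  parameterization would inflate the male mean by ≈ 0.8 y). Defaults:
  male 35.04 ± 9.58 y, 179.42 ± 6.60 cm, 77.23 ± 10.32 kg, 15.68 ± 4.55 %;
  female 32.25 ± 8.99 y, 167.19 ± 6.88 cm, 60.60 ± 8.73 kg, 22.04 ± 5.46 %.
- Relative VO₂max per sex × modality: 54.10 ± 6.93 (male TE), 51.92 ± 8.05
  (male CE), 48.79 ± 6.67 (female TE), 49.05 ± 6.64 (female CE)
  mL·min⁻¹·kg⁻¹, coupled to age via a Gaussian copula on (age, latent
  fitness) with correlation −0.4 — a typical cross-sectional age–fitness
  association, configurable, not an empirical claim.
- The RCP variable loads on latent fitness with correlation 0.9 (strong by
  construction: the classification variable is meant to track endurance
  capacity). Stratum means/SDs default to realistic endurance-athlete
  values — RCP speed 15.0 ± 1.8 (male) / 13.5 ± 1.6 (female) km·h⁻¹; RCP
  power 3.5 ± 0.6 / 3.1 ± 0.5 W·kg⁻¹ — chosen once as physiologically
  plausible placeholders since only the classification's *z-scores* matter
  downstream.
- Effort variables default to mostly-passing distributions (RER
  ~ N(1.14, 0.04), lactate ~ N(10, 2), fR ~ N(55, 8), Borg ∈ {18, 19, 20},
  HR = HRmax_pred − |N(5, 5)|, post-RCP gain ~ N(15, 3) truncated at 0), so
  a realistic minority of athletes fails ≥ 2 criteria and the filter has
  non-trivial work.
- Fat-free mass is computed from mass and body-fat % per record (never
  sampled), so the consistency invariant holds exactly; its cohort mean
  lands near the emulated population (≈ 65.1 vs 64.87 kg for males) as a
  consequence, not a constraint.

What the generator does **not** emulate: height–mass correlation (so the
derived BMI SD is wider than in a real cohort, ≈ 3.7 vs ≈ 2.6 kg·m⁻²),
training-history dynamics, inter-variable effort correlations, or real
breath-noise structure (breath series are built on demand in tests).
Passing tests therefore demonstrate correctness of the *pipeline
machinery* on data with the assumed moments and dependence — not that any
equation is accurate on real athletes.

`inject_predictions` uses the cohort's VO₂max values as the predictions
and manufactures observations `c0 + c1·pred + N(0, σ)`, so OLS recovery of
(c0, c1) is unbiased by construction — the recovery tests are consistency
checks of the estimator, not of a data-generating story. `contaminate`
plants exactly one named violation per affected record; note that a single
broken effort criterion is detectable at the criterion level but does not
alone fail the ≥ 6-of-7 rule — that is the rule's semantics, and the
round-trip tests assert exactly this two-level behaviour.

## Numerical choices

- Truncated-normal moment matching solves a 2-equation root problem
  (`scipy.optimize.root`), short-circuiting when truncation is inactive;
  solutions are cached per parameter tuple.
- Determinism: one `numpy` Generator seeded from the config; identical
  (config, seed) gives byte-identical CSV serializations.
- Unit conversions route through mL·min⁻¹, so any conversion cycle is a
  single multiply/divide pair per leg (round trips within 1e-9 relative).
- OLS agreement with a closed-form two-pass oracle is enforced to 1e-10 in
  tests; adjusted R² is computed from the same sums of squares.
- Problem sizes in the default test run (cohorts of 300–20 000; one 100k
  calibration check; 10⁶ z-draws; 200 × 5000 recovery replicates) keep the
  whole suite under ~1 minute on one CPU while leaving Monte-Carlo
  tolerances at 4 standard errors.

## Known limitations

- Registry coefficients are transcriptions maintained in-package; the
  registry contract is tested, the transcriptions themselves should be
  reviewed against the source editions before any substantive use (the
  declarative loader exists for exactly this).
- The ±3 SD screen's variable set and its within-sex computation are
  package choices where the emulated procedure is underspecified ("all
  testing variables"); both are parameters.
- The mean-difference and free-intercept C1 conventions can differ by
  orders of magnitude when the slope is far from 1; reports must carry the
  convention tag, and do.
- Whole-cohort headline metrics depend on the (synthetic) cohort's
  dependence structure and are not estimates of any real population's
  values.
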