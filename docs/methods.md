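# Methods

This note documents the model, the data fixtures, the synthetic survey
generator, and the numerical and design choices in `dietsim`. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Scope and model structure

`dietsim` implements a static, discrete-time, deterministic microsimulation
of population dietary change. There are no temporal dynamics and no
stochastic individual transitions: a scenario is a deterministic edit of the
population-average food-group intake table, and the health outcome
(fasting plasma triglycerides, mmol/L) is recomputed from a fitted
log-linear regression. Key structural assumptions inherited from this class
of model:

* risk-factor effects are independent and enter additively on the log-TG
  scale (linear dose–response in each nutrient);
* scenario edits act on population-average intakes, not on individual
  diets; covariates are held at their baseline sample means under every
  scenario;
* food-group composition is fixed: scaling a group scales every nutrient
  it contributes proportionally.

## Nutrient bookkeeping

The 25 tracked quantities (gram weight; energy including fibre;
macronutrients; added/free sugars; fibre; alcohol; retinol equivalents,
folate equivalents, B12, calcium, iodine, iron, sodium, zinc; four
fatty-acid fractions; long-chain omega-3; glycaemic index and load) use
fixed units (g, mg, µg, kJ per day) — readers never unit-convert. All
fields except glycaemic index are additive across groups. GI is treated as
a derived quality measure:

    GI = 100 · GL / CHO   (0 when CHO = 0)

summed tables re-derive GI from the summed GL and carbohydrate. This is the
standard relation between glycaemic load and index, and it reproduces the
reference modelled-intake table's printed GI (52.9) from its printed GL
(89.5) and carbohydrate (169) within rounding. A supplied GI must agree
with the derived value within ±0.3 (print-rounding slack); the packaged
baseline *totals* column is the one printed row that violates this (54.8 vs
54.5 derived), so it is stored as a cross-check table rather than as a
validated vector.

Internal arithmetic is never rounded; report writers round half away from
zero to the precision of the corresponding published table cell.

## Fixtures

`data/group_intakes_baseline.csv` encodes the published per-group baseline
intakes of the modelled survey population (606 women aged 19–50). The two
published intake tables disagree on the orientation of several
minimally-processed vs culinary-ingredient cells; the fixture adopts the
orientation that is internally consistent with the gram-weight and GI/GL
rows and with the modelled table (e.g. MP protein 26.6 g from 1898 g of
food, not 0.1 g). Column sums still match the printed totals to within
accumulated print rounding (≤ ~1 unit per nutrient; energy 7662.1 recomputed
vs 7661 printed).

The foods *added* by scenarios are specific healthy foods, not
baseline-group averages (added fruit is ~320 kJ/100 g; the baseline fruit
group, diluted by juices, is ~214 kJ/100 g). Their per-100 g profiles are
derived at load time by differencing the published modelled-intake
reference table against baseline and dividing by the grams added
(150/225/30/40 g for fruits/vegetables/nuts/fish). The derived fish profile
carries ≈ 2.3 g long-chain omega-3 per 100 g, satisfying the ≥ 800 mg/100 g
definition of the high-omega-3 group. `baseline_profiles()` exposes the
baseline-density alternative. Oil profiles for the substitution scenario
are package-constructed synthetic compositions (a butter/margarine-spread
mix vs an olive/canola-dominant blend), as the source names the oil types
but not their composition.

## Scenario engine

Edits are applied in order; tables are immutable. `scale_group` multiplies
every additive field (GI unchanged — GL and CHO scale together).
`add_food` adds grams × profile/100 to the target group and re-derives the
group GI. `substitute` removes and adds equal gram weights, optionally
across groups (the oil scenario removes the saturated-oil profile from the
processed-foods group, where spreads sit in the NOVA scheme, and adds the
unsaturated profile to culinary ingredients); any nutrient driven below
zero is floored at zero with a logged warning, since intakes are physical
quantities. Total gram weight is conserved by substitution before flooring.

The built-in library: S1 (PF × 0.5); S2 models 1–3 (S1 + MP × 1.25/1.50/
1.75); S3a models 1–5 (S1 + fish 40–200 g/d by 40); S3b models 1–4 (S1 +
nuts 10–40 g/d by 10); S4 (S1 + vegetables and/or fruits 75–300 g/d by 75);
S5 (S1 + the full factorial grid nuts {10,20,30,40} × vegetables
{75,150,225} × fruits {75,150,225}, optionally + fish {40,80,120}, with the
published combinations tagged); S6 (oil substitution 5–20 g/d, no S1 base).
The source reports only selected S5 combinations; the engine exposes the
whole grid for exploration and tags the named ones. Grid bounds and steps
are overridable from a YAML/JSON config, which can also declare custom
scenarios.

## Triglyceride regression

Ordinary least squares on log TG (log transform to approximate normality),
via statsmodels. Conventions:

* **AIC** = n·ln(RSS/n) + 2(k+1), constants dropped consistently across
  candidates; only differences matter. Backward stepwise deletes the single
  non-protected term whose removal gives the lowest AIC while that is
  strictly below the current AIC; categorical terms (smoking status,
  country of birth) are dropped as whole dummy blocks; ties break
  lexicographically on term id; the audit trail of (step, dropped term,
  AIC) is kept and is strictly decreasing. The protected set defaults to
  empty. Greedy backward search attains the exhaustive best-subset AIC on
  near-orthogonal designs (the regime the oracle tests exercise); on highly
  collinear designs greediness can, like any stepwise procedure, miss the
  global optimum.
* **Back-transformation**: point predictions are exp of the linear
  predictor (a median-type back-transform; the demonstration baseline 0.935
  sits near the survey median 0.90). Duan's smearing correction is
  available (`smearing=True`) and off by default.
* **CI**: delta method on the log scale, exp(x·β̂ ± z·√(xᵀΣ̂x)). This is
  the standard prediction-of-the-mean interval and yields asymmetric
  intervals such as (0.893, 0.979) around 0.935.
* **R²** is reported on the log scale; **RMSE** on the original mmol/L
  scale (back-transformed predictions vs observed TG).
* **Collinearity**: an exactly rank-deficient design raises an error naming
  the collinear columns (via the smallest singular vector); a condition
  number above 10⁶ (energy with macronutrients, typically) emits a warning
  and leaves resolution to stepwise.

`LogTriglycerideRegression` wraps this as a scikit-learn estimator
(`fit`/`predict`/`get_params`, fitted attributes with trailing
underscores), so it composes with sklearn tooling; the module-level
functions remain thin wrappers over the same code.

## Demonstration coefficients

The coefficients actually fitted to the restricted survey are published
only in an appendix that is not publicly archived, so exact reproduction of
the survey model is impossible from public material. The package therefore
ships `data/demo_coefficients.csv`, a nutrient-only log-TG model whose
header marks it as a non-survey stand-in. It was calibrated once, by
sign-constrained ridge least squares over the scenario-delta matrix, so
that (a) the packaged baseline intake predicts 0.935 mmol/L with 95% CI
(0.893, 0.979) — all sampling variance is carried on the intercept, since
no covariance was published — and (b) the built-in scenarios track the
published headline percent changes to within ~0.5 percentage points. It is
a demonstration artefact for the pipeline, not an estimate of the true
diet–TG relationship; fitting your own survey replaces it everywhere.

## Synthetic survey generator

Emulates the structure, not the individuals, of the restricted microdata:

* covariates are independent draws — truncated normals for age (19–50),
  BMI (> 14), HDL-C (> 0) and glucose (> 0) whose *truncated* moments match
  the published sample mean/SD (the underlying normal parameters are solved
  numerically, because the published moments describe the observed,
  range-restricted sample); categorical probabilities from the published
  counts. Truncation bounds are documented plausibility constants, not
  survey-derived. A `correlation_hook` field is reserved for future
  correlated generation; independence mirrors the downstream model's own
  assumption.
* per-group gram intakes are Gamma(mean = fixture group mean,
  CV = 0.5) — right-skewed and non-negative, a typical between-person
  spread for daily food-group intake; the source publishes only means.
* nutrients are grams × the group's per-gram baseline composition, then
  jittered by a unit-mean lognormal per nutrient (CV 0.10) representing
  within-group food choice. Without this jitter the 23 nutrient columns
  would be an exact rank-7 function of the group intakes and any
  multi-nutrient regression would be singular — a real survey has
  within-group variation for the same reason.
* log TG = β_true·x + N(0, σ), σ = 0.45 by default (a typical log-scale
  residual spread that keeps the generated median in the published IQR
  0.7–1.2); β_true defaults to the demonstration nutrient coefficients plus
  modest covariate effects, with the intercept recentred so the population
  geometric mean stays at the demonstration baseline.

What passing tests on this generator do **not** show about real data:
covariate–diet correlations, survey design effects (clustering, weights),
within-group composition that co-varies with total intake, measurement
error in 24-hour recalls, and any non-log-linear diet–biomarker dose
response.

## Problem sizes and numerical choices

The property suites run at sizes chosen to make their Monte-Carlo error
small relative to the asserted bounds while staying desk-scale: exhaustive
best-subset enumeration on 10 terms (2¹⁰ subsets, n = 400); CI coverage
over 100 replicates of n = 10,000 (aggregate coverage over the 12 true
nonzero coefficients is asserted ≥ 93%, each coefficient ≥ 87/100 — bounds
set from the Binomial(100, 0.95) tail); population-mean checks at
n = 50,000. A single zero-coefficient term survives backward AIC with
probability P(χ²₁ ≥ 2) ≈ 0.157, so the null-term drop-rate test asserts a
rate consistent with the theoretical ≈ 84%, not near-certain deletion.
Floating-point comparisons against published cells use half a unit in the
last printed digit (plus float slack); derived-GI agreement uses ±0.3.

## Known limitations

* Scenario arithmetic is reduce-then-add with independently chosen gram
  amounts (as the published scenarios are); strict gram-for-gram balancing
  is only enforced by `substitute`. No energy rebalancing to isocaloric
  diets and no linear-programming diet optimisation.
* Food-item-level ingestion and NOVA classification of a full composition
  database are out of scope; group-level tables and user-supplied per-100 g
  profiles are the inputs.
* No survey-weighted regression, mixed models, or bootstrap validation of
  the TG model.
* The added-food profiles are recovered from a published table by
  differencing and therefore inherit its print rounding (≲ 0.01 units per
  100 g).
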