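# Methods

This note documents the models, conventions and design choices behind
`dietchange`, and what its synthetic-data tests do and do not establish.

## The FFQ instrument and its conversion model

The package models a 64-item semi-quantitative FFQ with a 9-level frequency
scale. Only the endpoints of the scale are anchored by the instrument
("never", "≥4 times per day"); the intermediate rates are a documented
default mapping (0, ~6/year, 2/month, 1/week, 2–3/week, 5–6/week, 1/day,
2–3/day, 4/day) shipped as an editable, strictly-increasing table. Loaders
reject non-monotone tables, a non-zero "never" level, or a top level below
4/day.

Portions for staple foods, meat dishes and vegetables come from the selected
portion photograph (four plates of strictly increasing grams per class);
every other item uses a per-item standard portion scaled by sex (0.87 / 1.15)
and age-group (1.05 → 0.90) factors. The photograph gram values and scaling
factors are plausible defaults, not measured values, and are configuration
data.

Blank items contribute zero intake but count toward the missing fraction;
heavy missingness (>10% of items) is handled by exclusion rather than
imputation, since imputing habitual frequency codes would manufacture
intake. A missing portion photograph makes its item class contribute zero
and flags the record for exclusion.

Energy percent uses Atwater factors 4/4/9 kcal/g with dietary cholesterol
treated as a lipid at 9 kcal/g. These factors are a package convention chosen
because they reproduce the published cholesterol-E% arithmetic (0.15 g/day at
1546 kcal/day → 0.09 E%) and make protein+carbohydrate+fat E% sum to exactly
100 under a no-alcohol energy model. Alcohol is outside the nutrient list; if
an alcohol-bearing composition table were used, the E% denominator would need
revisiting.

## Diet quality scores

**HDS.** Quartile cut points are within-sex empirical quantiles with linear
interpolation (P25/P50/P75), computed separately at each visit, so the score
is a within-cohort relative measure: the cohort-mean HDS is pinned near 12 at
every time point by construction and only individual changes are informative.
Ranks are coded 0–3 (forced by the 8 × 3 = 24 maximum). Values exactly equal
to a cut point take the lower quartile's rank — a deterministic tie policy
the score's verbal definition leaves open.

**Modified DII.** The default z-score transform is the identity,
`contribution = w_p · z_p`, which makes the index exactly linear in the
effect weights; the original index's centered-percentile transform
`w_p · (2Φ(z_p) − 1)` is available via `transform="percentile"`. The 30
parameters (28 single-item intakes plus a merged caffeine parameter and tea)
and their global means/SDs are synthetic reference data — the original
index's 45-parameter global reference tables are distributed privately, not
in print — so the DII is validated structurally (parameter count, merged
caffeine, sign conventions, linearity) rather than numerically.

## Exclusion cascade

BMR uses the Schofield weight-based equations (women 30–60 y:
0.034·W + 3.538 MJ/d; men: 0.048·W + 3.653; >60 y: 0.038·W + 2.755 and
0.049·W + 2.459), converted at 239.0 kcal/MJ. The equations are isolated
behind `compute_bmr` so an alternative BMR model can be swapped in.

FIL percentile flags use within-sex empirical P1/P99 with linear
interpolation, computed separately per visit (pooled across exam years within
a visit — an assumption, since per-year computation is equally defensible);
boundary values are retained. Strata below a configurable floor (default 100
records) suppress the flags with a warning rather than flag on unstable
percentiles.

The 10 ± 1 year visit window is treated as the closed interval [9, 11] years
(days/365.25). Exclusion is evaluated per rule per visit and an individual is
excluded if flagged at either visit; because the final set is the union of
per-rule flag sets, rule evaluation order cannot affect it.

## Lipid calibration

The published affine maps are implemented verbatim, including the
triglyceride slope of 0.139, which is strikingly small but printed as such.
A consequence the generator deliberately reproduces: Reflotron-era calibrated
triglycerides are compressed onto [0.888, ∞) mmol/l, which is why visit-1
triglyceride SDs are an order of magnitude below visit-2 (enzymatic-era) SDs.
Device is taken from an explicit column when present, otherwise inferred from
the exam date (strictly before 2009-09-09 → Reflotron; the boundary day is
treated as enzymatic).

## Outcome models

Models are ordinary least squares, always fitted per sex, with listwise
deletion of incomplete cases (counted and logged; percent changes with a zero
baseline are flagged undefined rather than silently dropped elsewhere).
Categorical covariates are reference-coded with the most frequent level as
reference. Rank-deficient designs raise an error naming the aliased columns
(via pivoted QR). Significance is a fixed α = 0.05 with no multiplicity
correction, the convention in this analysis tradition; Benjamini–Hochberg is
available as an opt-in helper.

"R² excluding covariates" is a refit on the same rows with only the dietary
exposure terms and an intercept — not a partial R² — because its purpose is
to quantify how much outcome variance the diet changes explain on their own.
Since the diet-only model is nested in the full model on identical rows,
R²_diet ≤ R²_full always holds.

Adjusted stratum means are marginal predictions: fit value ~ stratum
indicators + covariates, then average the model's predictions over the whole
observed covariate distribution with the stratum fixed, with delta-method
(t-based) CIs. Model-based CIs on adjusted means were chosen (over individual-level
percent-change CIs, an equally defensible reading) and are tested against a
prediction-averaging oracle.

The sensitivity refits mirror the descriptive checks of the main analysis:
10-year change (absolute or percent) as outcome, and adjustment for baseline
BMI or 10-year BMI change (a potential mediator). They report beta/p shifts
against the main model and make no causal mediation claims.

## Synthetic cohort generator

The generator's defaults are the study conditions the package is tested
under, chosen once:

- ~52% women; baseline age groups 30/40/50/60 with probabilities
  0.04/0.47/0.485/0.005; baseline years uniform 1996–2004; visit intervals
  uniform on [9.05, 10.95] years (kept off the closed QC boundaries so
  day-rounding cannot cross them).
- FFQ codes: per item, a discretised-normal marginal over the 9 levels
  centred on an item-typical level (shifted by a global offset of −1.0 and a
  subject "appetite" effect, SD 0.35), coupled across visits by a latent
  Gaussian copula with ρ = 0.5, and drifted by −0.15 levels at visit 2. The
  offset and drift were fixed so that mean reported energy sits near
  ~1610/2070 kcal (women/men) at visit 1 with a ~9–10% decline at visit 2,
  and FIL centres near 1.1. Real FFQ data have item-set changes, secular
  portion drift and differential under-reporting that the generator does not
  model.
- Anthropometry, baseline lipids and blood pressure are drawn from normal
  (triglycerides: lognormal Reflotron-raw) distributions matching typical
  middle-aged Scandinavian screening values; covariate marginals (education
  2 levels, smoking 3, activity 4) use realistic per-sex frequencies with no
  joint structure claimed.
- Visit-2 outcomes follow an explicit linear model: intercept + tracking of
  the baseline outcome (BMI 0.92, cholesterol 0.55, triglycerides 0.60, SBP
  0.55) + fixed covariate effects + injected exposure betas × realised
  percent changes + Gaussian noise (residual SDs 1.8 / 0.84 / 0.35 / 13.0).
  Exposures are *not* drawn directly — they are derived by the package's own
  FFQ/scoring code from the generated codes — so parameter-recovery tests
  exercise the entire chain. Residual normality is an assumption of
  convenience; nothing downstream depends on it beyond OLS inference.
- Lipids are recorded on the device scale of each exam date's era by
  inverting the calibration maps, with raw readings floored at 0.05 mmol/l
  (relevant for <1% of Reflotron-era visit-2 triglycerides, whose
  enzymatic-scale values below 0.888 mmol/l have no positive Reflotron
  preimage).
- QC violations are injected on disjoint subject sets per rule so the
  returned ledger matches the cascade's per-rule flags exactly; the FIL
  percentile rule cannot be injected at a fixed rate (it is relative to the
  realised distribution) and is instead verified against a sort-based oracle.

## Problem sizes and numerical checks

Test and example problem sizes were chosen to keep the whole suite in tens of
seconds on one CPU while leaving Monte-Carlo error well inside the asserted
bands: OLS exactness against a normal-equations oracle at n ≤ 100 (1e-10),
type-I error over 200 replicates of n = 2,000 (band 0.05 ± 0.03 per
exposure), 3-SE recovery over 100 replicates of n = 5,000, end-to-end
pipeline checks at n ≈ 300–5,000. The R²-decomposition check uses a
strong-tracking/weak-diet regime (diet betas of a few thousandths of a BMI
unit per percent change) in which diet-only R² stays under 2% while the full
model exceeds 60% for BMI — the qualitative pattern a tracking-dominated
longitudinal risk factor shows.

## Known limitations

- The synthetic food composition table, DII reference and portion data are
  internally consistent stand-ins, not measured values; absolute nutrient
  levels are only order-of-magnitude realistic.
- Passing parameter-recovery tests shows the pipeline is self-consistent and
  the estimator well calibrated under its own generative model; it cannot
  validate the FFQ instrument itself against true intake.
- Alcohol, micronutrients and the 84-item instrument variant are out of
  scope; only the 64-item instrument is modelled.
- Percent-change exposures are undefined at zero baselines (dropped
  listwise, counted); the DII percent change is numerically unstable when
  baseline DII is near zero — its models are structural placeholders unless
  effects are injected on the DII scale.
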