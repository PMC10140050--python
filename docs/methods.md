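# Methods

This note documents the analytic procedure implemented by `asthmactl`, its
assumptions, the tunable parameters, and the design choices made where the
design was genuinely open.

## Study design

The analysis is a cross-sectional assessment embedded in a retrospective
cohort. Each patient is anchored at an *index date* — the date of their
first valid Asthma Control Test (ACT) — and two quantities are measured at
that anchor: asthma control (the outcome) and GINA treatment step (the
exposure), the latter derived from prescriptions written before the ACT's
recall period. Prevalence ratios of not-well-controlled asthma by step are
then estimated with adjustment for a fixed confounder set.

## ACT validity and control status

The ACT is five items, each 1–5, total 5–25, with a 4-week recall period.
A total ≤ 19 is *not well-controlled*; ≥ 20 is *well-controlled*. An ACT
record is valid when (1) all five items are present, (2) no other ACT for
the patient shares its date, and (3) no other ACT precedes it by 1–28 days.

Two measurements inside one recall window cannot be disambiguated, which
motivates rules 2–3. The 28-day rule is applied **backward-looking only**:
a later repeat is invalidated by an earlier measurement, never the reverse.
A symmetric rule would let a repeat taken weeks later retroactively
invalidate a patient's otherwise-first valid ACT, which is incompatible
with defining the index as the *first* valid measurement. Incomplete ACT
records still count as "another measurement" for rules 2–3: an incomplete
administration still marks an ACT event inside the recall window.

## Inclusion / exclusion

Stages are applied in a fixed order and logged (counts are order-dependent;
final membership is not, except through the index definition):

1. asthma diagnosis (prefix match on ICD-9 `493`, ICD-10 `J45`, SNOMED
   `H33`) on or before index — for patients with no valid ACT, who have no
   index, the check falls back to ever-recorded codes; they are removed at
   the next stage regardless;
2. valid index ACT within the study window 2015-01-01..2018-12-31
   (inclusive);
3. ≥ 1 prescription of an asthma-treatment class (every class except OCS
   and non-asthma drugs) in the exposure window `[index−210, index−29]`
   days, both ends closed — 210 = 182-day treatment lookback + 28-day
   recall period, and prescriptions inside the recall period do not count;
4. any encounter dated ≥ 182 days before index ("6 months" is fixed at 182
   days everywhere);
5. no COPD diagnosis on or before index (default stems ICD-9 490–492, 494,
   496; ICD-10 J40–J44, J47; configurable, since no canonical list is
   universal);
6. known calendar year of birth.

## GINA step classification

Exposure-window prescriptions are summarized into a medication profile and
mapped to a step. Parameters and conventions:

- **ICS daily dose** = frequency/day × dose amount × strength, in mcg/day
  (mg strengths × 1000 first). Missing sig fields (frequency, dose amount,
  dose unit) are imputed with the per-NDC mode over the entire prescription
  table; ties break to the smallest value (deterministic and conservative —
  a lower imputed dose can only lower the step). An NDC with no observed
  value for a field leaves it missing.
- **Dose levels** come from a per-ingredient threshold table
  (`dose_thresholds.yaml`, mcg/day): dose ≤ low_max → low, ≤ medium_max →
  medium, else high. The shipped defaults are the GINA-2018 adult bounds
  for six common ingredients and are fully overridable. Doses below any
  published floor are still "low": the rules only need the 3-level split.
- **Open combinations**: a standalone ICS prescription within 30 days
  (inclusive, absolute difference) of a LABA prescription is treated as an
  ICS/LABA combination; farther apart, the ICS counts as ICS-only and the
  LABA is ignored (it is not monotherapy in that case). Both components
  must lie inside the exposure window.
- **Nearest-to-index selection**: among multiple ICS or ICS/LABA
  prescriptions, only those closest in days to the index contribute the
  dose. Equidistant prescriptions of the *same* ingredient have their daily
  doses summed (same-day refills of one product); equidistant different
  ingredients resolve to the highest resulting level. This tie convention
  is a choice — prescription data does not say which product the patient
  actually used — and is flagged in the per-patient rationale trail.
- **Relievers** (SABA, SAMA, SABA/SAMA) collapse to one flag; reliever-only
  is Step 1 and reliever presence never changes any controller-defined step.
- **OCS** is assumed short-course (supply ≤ 28 days) and never affects the
  step; day-supply cannot be computed reliably from prescription sigs.

Rules are evaluated highest step first, so co-prescriptions resolve to the
most intensive regimen: biologic → 5; medium/high ICS-LABA, high ICS,
LAMA + any ICS-containing product, or medium ICS + LTRA/methylxanthine → 4;
low ICS-LABA, medium ICS, or low ICS + LTRA/methylxanthine → 3; low ICS, or
a sole LTRA / mast-cell stabilizer / methylxanthine → 2; reliever with no
controller → 1. Everything else — LABA or LAMA monotherapy, OCS only,
ambiguous controller combinations, no prescriptions — is Undefined.

When an ICS-containing component's dose could not be computed even after
imputation, the rules are evaluated under every low/high substitution for
the unknown level: if all substitutions agree (e.g. LAMA + ICS is Step 4 at
any dose) the common step is assigned; otherwise the dose is genuinely
needed and the patient is Undefined.

## Covariates

Derived at index: age = index calendar year − birth year; race collapsed to
white / african_american / other, with *unknown* for absent or conflicting
entries; ethnicity hispanic / non_hispanic, *missing* when absent or
conflicting (the conflict rule mirrors race; the source definitions do not
address it); smoking with precedence current-on-closest-record >
ever-former > consistently-non-smoker > unknown, ignoring records after
index; BMI from the on-index or nearest prior observation, categorized with
WHO left-closed cuts 18.5/25/30; visit type from the index-day encounter's
specialty (Internal/General/Family Medicine → primary care; Allergy and
Immunology, Pulmonary Disease, Emergency Medicine → specialist; anything
else → other; none recorded → unknown), with specialist > primary care >
other precedence for multiple same-day encounters. Same-day ties for
nearest records take the last-written row. Missingness is modelled as
explicit *unknown*/*missing* levels, never imputed.

## Prevalence model

The outcome indicator is y = 1 for not-well-controlled. The model is
Poisson regression with log link on the binary outcome — the "modified
Poisson" estimator — because the outcome is common (~30%) and odds ratios
would overstate the prevalence ratio. The design matrix holds an intercept,
five step indicators (Step 1 reference), continuous age in years, and
indicator blocks for race (white ref.), ethnicity (non-hispanic ref.),
smoking (non-smoker ref.), BMI category (normal ref.; categorical so that
patients with missing BMI stay in the model) and visit type (primary-care
ref.). Unused levels are dropped from the matrix; genuinely collinear
designs raise an error naming the columns.

Fitting is Newton scoring (IRLS), initialized at β = 0 with the intercept
at log(mean y), declared converged when max |score| < 1e-8 (≤ 100
iterations), with a step-halving guard on the log link; after the tolerance
is met, iterations continue while the score still shrinks, so saturated
group means are reproduced to machine precision. The covariance is the HC0
sandwich A⁻¹BA⁻¹ with A = Σ μ̂ᵢxᵢxᵢᵀ and B = Σ(yᵢ−μ̂ᵢ)²xᵢxᵢᵀ — no
small-sample correction, appropriate for n ≫ p. CIs are Wald:
exp(β ± 1.959964·SE). Two exact properties anchor the implementation and
are enforced in tests: with step indicators only, fitted PRs equal ratios
of observed proportions; and in the two-group model the robust SE equals
√((1−p₂)/(n₂p₂) + (1−p₁)/(n₁p₁)). An independent GLM implementation
(statsmodels) serves as a cross-check oracle in the test suite only.

Percentages in the descriptive tables are rounded half-up to one decimal.

## Synthetic generator

The generator plants, per patient: a GINA step from a 6-component mixture
(default shares 0.345/0.241/0.140/0.251/0.011/0.012 for Steps 1–5 and
Undefined), covariates from per-step marginal distributions chosen to
resemble a large US outpatient treated-asthma population (ages 12–88,
~36% male, ~20% Hispanic, obesity rising with step, specialist visits
concentrated in higher steps), and a control status drawn from a
**log-linear** outcome model: log P(not well-controlled) = intercept +
step and covariate effects, age centered at 44 years. Defaults: intercept
log 0.25; step log-PRs log(0.857, 0.962, 1.160, 1.529, 1.113) for Steps
2–5/Undefined; age +0.004/yr; smoking former +0.10, current +0.30; BMI
underweight +0.10, overweight +0.05, obese +0.20, unknown −0.05; race,
ethnicity and visit-type effects zero. Because the model is log-linear,
the planted prevalence ratios are exactly the exponentiated coefficients,
which is what makes parameter-recovery experiments well-posed.
Configurations that admit probabilities above 1 are rejected at validation
rather than clamped — clamping would silently bias recovery.

Records then realize the plant: an asthma diagnosis 250–600 days before
index, an activity encounter 182–420 days before, an index-day encounter
carrying the visit-type specialty, exposure-window prescriptions drawn from
a regimen menu for the planted step (including medium-ICS-in-mg, open
ICS+LABA, ICS+LTRA and decoy-earlier-prescription variants so that unit
conversion, pairing and nearest-selection are all exercised), optional
reliever/OCS/non-asthma extras, observations realizing smoking and BMI, and
an index ACT whose items are drawn uniformly from all compositions of a
score in [5,19] or [20,25]. Index dates are uniform over a mid-study year
(2016-07-01 ± 1 yr) so every window fits inside the study period.

Noise patients violate exactly one criterion each (default 2% per reason;
configurable): no asthma code; no valid ACT (one missing item, a same-day
duplicate, or an incomplete first ACT with a complete repeat 1–27 days
later — the repeat alone would not invalidate the first under the
backward-looking rule); treatment only inside the recall period; first
encounter 100 days before index; a COPD code; or a missing birth year. A
fraction of ICS-bearing prescriptions (default 10%) has a sig field
blanked, but only when a complete same-NDC donor row already exists, so
mode imputation is always well-defined and planted steps remain exactly
recoverable.

Randomness is one stream split per patient by counter
(`default_rng([seed, i])`), so output is deterministic given the seed and
independent of generation order; written datasets are byte-identical across
reruns.

**What the generator does not emulate** — and hence what passing round-trip
tests do *not* establish about real data: free-text sigs and NLP extraction
error, real NDC/ingredient diversity, longitudinal treatment switching,
within-step covariate correlation (covariates are sampled independently
within step from marginal distributions), care-seeking dynamics, and
date-shifting de-identification. Recovery of planted structure shows the
pipeline implements its stated rules correctly, not that the rules identify
true treatment intensity in any particular EMR.

## Problem sizes

The test suite uses 2,000-patient datasets for round-trip phenotyping,
20,000 draws for mixture-share checks, 10,000 fuzzed profiles for the
classifier invariants, and 200 replicates of n = 5,000 for parameter
recovery and CI coverage; the acceptance script regenerates a 20,000-patient
population. These sizes give Monte-Carlo error comfortably below the
assertion bounds (e.g. binomial SE ≈ 0.3 percentage points on step shares
at n = 20,000) while keeping a full run in single-digit minutes on one CPU.

## Known limitations

- The step rules encode the 2018 treatment ladder; the 2019 as-needed
  ICS-formoterol Step-1 option is deliberately not implemented.
- Prescriptions measure prescriber intent, not adherence or actual use.
- The equidistant-prescription tie rule (sum same ingredient, max level
  across ingredients) is a convention; alternatives (take the latest, take
  the mean) would change a small number of assignments.
- The childhood ACT (ages 4–11) is not implemented; synthetic ages start
  at 12.
- Attrition counts (not final membership) depend on stage order.
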