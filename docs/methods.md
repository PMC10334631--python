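# Methods

## The screening problem

The pipeline screens every prescribed (non-anticancer) drug for association
with mortality in a cancer cohort built from claims tables.  The unit of
analysis is one drug code at ATC level 2 (3-character therapeutic group) or
level 4 (5-character chemical subgroup); the per-drug contrast is *past
1-year incident users* versus *nonusers* at the study-entry landmark, with
prevalent users excluded.  Two outcomes are analyzed: all-cause mortality
and cancer-specific mortality, the latter with cause-specific hazards
(deaths from other causes censor at the death date).  Discovery-stage
multiplicity is controlled at FDR q = 0.05 per outcome × ATC level family
with the Benjamini–Hochberg step-up rule (implemented directly and verified
against an exhaustive oracle; a Benjamini–Yekutieli variant is available
for sensitivity); discovery signals must replicate in an independent
validation half at p < 0.05 with a direction-consistent hazard ratio.

Key design positions, with the reasoning where the choice was genuinely
open:

- **Exposure windows in whole days.**  "1–1.5 years before entry" is fixed
  to half-open windows at day resolution: far = [t₀−548 d, t₀−365 d), near
  = [t₀−365 d, t₀).  A prescription on t₀ itself counts as post-entry and is
  ignored — exposure is strictly pre-landmark.  Far-window use takes
  precedence (prevalent beats incident), which is what makes the incident
  definition a genuine new-user design.
- **Prevalent users are excluded** from that drug's model rather than
  pooled with nonusers; comparing prevalent users with nonusers is the
  classic survivor-bias trap.  `prevalent_handling="recode_nonuser"`
  exists for sensitivity analysis.
- **Washout keys on entry date** (first treatment), not diagnosis date:
  cases entering within the first `washout_years` (default 2) of data
  coverage are removed.
- **Covariate adjustment is fully categorical**: sex, the six age bands,
  the six treatment categories (staging proxy) and three Charlson levels,
  dummy-expanded against the first level of each enumeration.  Age enters
  as the banded factor — the screen must be uniform across hundreds of
  drugs, and the bands are what the cohort table reports.
- **Ties**: Efron's method by default; Breslow available.  Validation
  p-values are two-sided Wald.
- **Eligibility**: a drug enters a family only with ≥ `min_users_per_arm`
  (default 10) incident users *and* nonusers in the split; degenerate or
  non-converged fits are reported with a reason and excluded from the BH
  family size m, since they carry no test.

## The synthetic-claims generator

`synthetic_claims` emulates the *structure* of a national claims sample for
a colorectal-cancer cohort, not any real population:

- **Covariates.**  Independent categorical draws with defaults matching a
  published discovery set of n = 1,309: 66.0% male; age bands 3.7 / 10.5 /
  22.8 / 29.9 / 26.4 / 6.7%; treatment categories 19.4% operation-only,
  11.2% colonoscopy-only, 1.6 / 26.2 / 19.8% operation+adjuvant
  combinations, 21.8% chemo/radio without operation; Charlson 7.6 / 31.2 /
  61.2%.  Entry is uniform over 2004-01-01..2015-12-31 inside coverage
  2002-01-01..2015-12-31 (the two pre-entry years provide the washout and
  the 1.5-year exposure lookback).
- **Records.**  Each patient gets one C18/C19/C20 diagnosis 0–30 days
  before entry and the treatment records realizing the drawn category,
  starting exactly at entry (so the cohort builder's derived t₀ and
  category equal the planted ones).  Per drug, a patient is incident with
  probability `p_incident`, prevalent with `p_prevalent`, else a nonuser;
  prescription counts are Poisson with mean `rx_rate` per exposed year
  (minimum one), placed uniformly in the corresponding window.  Prevalent
  users continue prescribing into the near window with probability 0.5,
  deliberately exercising the far-use-precedence rule.
- **Survival.**  Two independent latent Weibull times (cancer and
  other-cause death) under proportional hazards:
  S(t) = exp(−m·(t/λ)^k) with multiplier m = exp(covariate log-HRs +
  Σ planted drug log-HRs over the patient's incident exposures), sampled by
  inverse transform.  A drug's `log_hr_cancer_specific` scales the cancer
  hazard and `log_hr_all_cause` the other-cause hazard; setting both to β
  scales the all-cause hazard by exactly e^β, so the all-cause Cox screen
  is correctly specified under the generator.  The earlier latent time
  (rounded up to a whole day, ≥ 1) is the death with its cause;
  administrative censoring applies at the coverage end.  This two-hazard
  latent-minimum construction is the simplest competing-risk generator
  whose cause-specific Cox fits downstream are correctly specified.

**Default hazard scales.**  The demo scenario uses Weibull(0.9, 35 000 d)
for cancer and Weibull(1.1, 50 000 d) for other-cause death, calibrated by
simulation so mean follow-up ≈ 54 months under the default covariate
effects.  The replicate studies (estimator calibration, error control,
power) use `high_mortality_config` — Weibull(0.9, 12 000 d) /
Weibull(1.1, 17 000 d), ≈ 60% all-cause deaths — so per-drug event counts
stay informative at n of a few thousand.

**What the generator does not emulate**: confounding by indication
(exposure is independent of covariates given the config), non-proportional
hazards, informative censoring, dose/duration/adherence structure,
correlated co-prescribing, and calendar trends.  Passing tests therefore
demonstrate that the pipeline recovers what it claims *under its own model
assumptions* — unbiased log-HRs, nominal CI coverage, FDR control — not
that any real-data signal is causal.

## Verification strategy and problem sizes

- Exposure classification and the BH step-up rule are checked for exact
  agreement with brute-force oracles (10,000 random prescription sets;
  1,000 random p-vectors of length ≤ 12), and BH additionally against
  `statsmodels.multipletests`.
- The Cox solver is cross-validated against `lifelines` (Efron) and
  `statsmodels` (Breslow) to ~1e-6, and against the closed-form two-group
  exponential rate ratio.  Results are bitwise invariant to patient order
  (rows are canonically sorted before fitting).
- A full simulator round trip (n = 2,000, 50 drugs) must reproduce every
  ground-truth exposure class through the real bundle → cohort → exposure
  path at both ATC levels.
- Estimator calibration uses 200 replicates of n = 2,000 with one drug
  planted at HR 2 (p_incident 0.10): mean log-HR within ±0.05 of ln 2,
  CI coverage in [0.92, 0.98].  Error control uses 100 replicates of a
  200-null-drug screen at n = 2,000 (all-cause family at level 4, the
  configuration where miscalibration would surface); under the global null
  the false-discovery proportion per replicate is 1{R>0}, and its mean
  must stay within 3 Monte-Carlo SEs of q.  Power uses one HR-2 drug
  (p_incident 0.15) among 199 nulls at n = 4,000, requiring validation in
  ≥ 80% of 100 replicates.  `scripts/acceptance.py` re-measures the same
  quantities at reduced replicate counts (50/40/40) as a quick
  reproduction entry point.

## Numerical choices and degenerate inputs

- Newton iteration on the log partial likelihood with step-halving;
  convergence at max |score| < 1e-8.  Monotone-likelihood/separation is
  flagged (|β| > 15 or SE > 50) and reported as non-converged rather than
  returning a meaningless estimate.
- The linear predictor is max-shifted before exponentiation; the shift
  cancels exactly in the likelihood, score and information.
- Adjustment columns constant within a subset (e.g. an age band absent
  from one split) are dropped from that fit only; the drug indicator is
  always retained.
- Volcano y-values floor the adjusted p at 1e-300 before −log₁₀.
  Validation-stage volcanoes plot the raw validation p against the 0.05
  threshold, since FDR adjustment is a discovery-stage concept.
- The 1:1 split takes |discovery| = round(ratio·n) patients by seeded
  permutation of the patient-id-sorted cohort, making labels a function of
  (patient set, seed), not of row order.
- Ceiling event times to whole days creates realistic tie structure; with
  Efron's correction the induced bias is negligible (measured ≈ −0.004 on
  a planted log-HR of 0.693).

## Known limitations

- The screen is a signal-detection device, not a causal inference engine:
  no propensity adjustment, no time-varying exposure after the landmark,
  no subgroup or interaction analyses.
- Charlson comorbidity is consumed as a precomputed 3-level category; the
  mapping from raw diagnosis histories is deployment-specific and out of
  scope.
- The anticancer exclusion list is a configuration input (ATC prefix set,
  default L01/L02), not a curated registry.
- Cause-of-death dichotomization (target cancer vs other) is an ingestion
  contract of the data provider or simulator.
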