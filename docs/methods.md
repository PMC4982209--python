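# Methods

`icuecon` re-implements, as a tested pipeline, a one-year economic
evaluation of a ventilated ICU cohort with moderate-to-severe ARDS: 795
patients randomised between conventional mechanical ventilation and
high-frequency oscillatory ventilation (HFOV), followed for a year with
daily in-ICU case-report forms and postal questionnaires at 6 and 12
months. Because no patient-level data from such trials are publicly
deposited, the pipeline runs end to end on a synthetic cohort whose
marginal structure is calibrated to the published summary statistics.
This note records the models, the defaults and why, the numerical
choices, and what the synthetic data can and cannot show.

## Synthetic cohort generator

The generator emulates the *study design*, not the disease process: one
row per randomised patient, one row per ICU day, one row per eligible
survivor per questionnaire wave. Its defaults are the published cohort
moments — n = 795, 1:1 allocation, age N(55.4, 16.8²) years (clipped to
[16, 100]), 37.7 % female, APACHE II N(21.8, 6.1²) rounded and clipped to
the instrument's 0–71 range, PaO2:FiO2 N(15.1, 5.0²) kPa, 58.6 %
pneumonia as prime condition, 13.6 % surgical admissions.

**Survival.** One-year mortality is 51.2 %. Death days are a
two-component mixture: with probability `early_death_fraction` a death is
uniform on days 1–30, otherwise uniform on days 31–365. This is the
simplest model reproducing the reported curve shape — a steep early fall
with low, stable mortality after day 60. The default
`early_death_fraction = 0.9` follows from the published counts: 96 % of
deaths occurred in hospital and non-survivors' mean ICU stay was ~14
days, so roughly nine in ten deaths fall within the first month.

**Lengths of stay.** ICU stay is lognormal, moment-matched to mean 17.0
and SD 16.5 days and rounded to whole days (the rounding bias is < 0.001
days); the post-ICU hospital extension is an independent non-negative
lognormal chosen so total hospital stay has mean 33.6 days with a
dispersion consistent with the published SD of 43.1. Stay and survival
are drawn *independently*: only marginal moments are published, and any
joint structure would be invention. Consequently a synthetic patient can
"die" before their drawn discharge day; the costing engine prices the
drawn stay, and in-hospital versus post-discharge death classification
uses the drawn timelines consistently. Ventilated days are a Beta(κ=10)
fraction of the ICU stay with mean `vent_days_mean / icu_los_mean`. The
trial does not report mean ventilated days; the default of 11 days is a
calibration constant (adjustable in config) chosen with the survival and
utility calibrations so the pipeline's quality-adjusted survival lands
near the published headline value.

**Care mix after ICU.** Post-ICU days are split between ward and
high-dependency (HDU) care, with 75 % of step-down time at HDU level plus
occasional ICU readmissions (18 % of patients, ~7 days). This mix is
calibrated so the post-ICU daily cost under the bundled unit costs
(~£680/day) approaches the published £732/day and the ICU share of
hospital cost (~77 %) approaches the published ~70 %. The `hdu_days`
patient field exists precisely because a single ward rate of £297/day
cannot reproduce either figure.

**Questionnaires and non-response.** Survivors alive at day 182 (365)
are eligible for the 6- (12-) month wave. Non-response follows a
logistic model in standardised age and APACHE II with base rates 41.1 %
and 47.2 % (the complements of the published 58.9 %/52.8 % response
rates) and slope `nonresponse_mar_strength = 0.3` log-odds per SD — the
published finding is directional only (responders were younger with
lower APACHE II), so the magnitude is a design choice. Missingness is
therefore missing-at-random given observed covariates, which is exactly
the regime the imputation stage assumes.

**EQ-5D states.** A latent utility is drawn from a normal with SD 0.37
(the published survivor SD) and mapped to the admissible EQ-5D-3L state
with the nearest tariff value. Nearest-value quantisation onto a bounded,
uneven grid biases the sample mean (≈ −0.02 at the ceiling), so the
latent mean is first calibrated by a Brent root-find on the exact
quantised expectation; the mapped means then hit the targets (0.5622 at
6 months, 0.5831 at 12) within sampling error.

**Seeding.** One master seed; each table draws from its own child stream
(`numpy` `SeedSequence.spawn`), so regenerating one table never perturbs
the others.

What the generator does *not* emulate: correlation between severity and
survival or cost (covariates are drawn independently of outcome, which is
also what makes the baseline-table null calibration checkable), any
HFOV physiological mechanism, seasonal or centre effects, and within-
patient longitudinal correlation of EQ-5D between waves. Passing tests
therefore validate the *estimators* under the published marginals, not
any joint structure of the real cohort.

## EQ-5D-3L scoring

Utilities use the standard UK time-trade-off value set in its additive
decrement form: u = 1 − 0.081·[any problem] − Σ dimension decrements −
0.269·[any level 3], with per-dimension level-2/3 decrements (mobility
0.069/0.314, self-care 0.104/0.214, usual activities 0.036/0.094,
pain/discomfort 0.123/0.386, anxiety/depression 0.071/0.236). The worst
state "33333" scores −0.594; the unconscious state is valued at −0.4.
The coefficients ship as a replaceable YAML file; tests enumerate all 243
states against a brute-force recomputation. Partially missing EQ-5D
responses are rejected rather than part-scored: wave means use all
complete returned questionnaires at that wave ("all available
questionnaires"), deliberately a larger set than the both-wave complete
cases used for costs. Population comparisons use Welch's t against
age-band reference means; the reference table ships with an assumed
reference sample size (500) that affects only degrees of freedom.

## Micro-costing

Bottom-up costing multiplies observed volumes by unit costs per pathway:

* **ICU day**: a rate per organ-support count (tiered 0–6, mirroring how
  national critical-care reference costs tier by organs supported;
  unconfigured tiers raise rather than extrapolate), plus renal
  replacement, X-rays, chest drains and per-unit drug costs, plus a
  fixed daily ventilation cost on ventilated days —
  (machine price / 5-year life + annual maintenance) / 365 utilisation
  days — and one single-use circuit per ventilated patient.
* **Post-ICU**: step-down days at ward/HDU rates, readmission days at
  the critical-care rate, an emergency-transfer fee for patients moved
  to another hospital, and itemised serious adverse events.
* **Post-hospital**: NHS visits/inpatient days/aids from the
  questionnaires; patient and carer travel miles at a petrol rate plus
  lost earnings and out-of-pocket amounts (pass-through, not unit-cost
  scaled). Defined only when *both* waves were returned — the two waves
  jointly cover the year — otherwise missing and left to imputation.
  Patients who died within the year accrue zero post-hospital cost by
  definition rather than missing; the imputation stage concerns
  survivors only. A consequence is that post-discharge resource use of
  within-year decedents is not counted, which slightly understates the
  societal total.

All amounts are in 2012 GBP; a hospital pay-and-prices index restates
other price years. The bundled unit-cost table is **illustrative** — the
original study's unit costs live in an unavailable supplement — with one
anchored value (ward day £297, the published post-ICU daily quartile);
every figure is replaceable config, and all costing tests that assert
absolute numbers derive them from the bundled file itself.

## Quality-adjusted survival

The cohort year is partitioned at the mean ventilated days t_v and at
91.3 / 182.6 / 274.0 / 365 days (3/6/9/12 months). The estimate is

QALY = −0.4 · t_v/365.25 + u3·A(t_v, 91.3) + u6·A(91.3, 182.6)
     + u9·A(182.6, 274) + u12·A(274, 365),

where A(a,b) is the area under the Kaplan-Meier curve over [a,b] in
years (exact step-function integration, 365.25 d/yr) and u6, u12 are the
survivor wave means. With only two assessments, the "linear change
between assessments" rule pins u9 = (u6+u12)/2 and, by backward
extrapolation of the same line, u3 = u6 − (u12−u6)/2. Anchoring the
first post-ventilation period at u3 (rather than 0 or u6) is a genuine
choice; the alternatives shift the cohort QALY by roughly ±0.03. The
ventilation term uses the *cohort mean* of ventilated days — matching
the stated procedure — not per-patient integration, and must end inside
the first period (t_v < 91.3 d enforced). The KM estimator is written
directly in numpy (events precede censorings at ties) because it runs
inside the patient-level bootstrap (1,000 resamples, percentile 95 % CI,
seeded); tests check it against both a brute-force product-limit oracle
and lifelines. Subgroup mortality is summarised by maximum-likelihood
logistic odds ratios adjusted for sex and PaO2:FiO2, with perfect or
quasi-separation reported as an explicit condition rather than a huge
Wald interval.

## Missing post-hospital costs

Post-hospital NHS and patient/carer costs are imputed among one-year
survivors by chained equations at the level of the two annual component
totals, not individual resource items. The conditional model is a
truncated Bayesian normal regression: per variable, regression
parameters are drawn from their posterior given complete cases
(σ² from a scaled inverse-χ², β from its conditional normal), and
missing values are drawn from the predictive normal truncated below at
the floor (zero), so imputations respect non-negativity by model rather
than by post-hoc clipping. Predictive mean matching was evaluated first
and rejected: its Rubin-pooled intervals undercovered (≈90 % against a
95 % nominal level in a 500-replicate calibration study), a known
weakness of PMM for small-m pooled means, whereas the truncated
regression achieves ≈94 % coverage with bias ≈0.2 % of the outcome SD.
Each of the m = 10 datasets comes from an independent chain (10 cycles
by default) so between-imputation variance is not deflated by
autocorrelation. Estimates pool by Rubin's rules with the standard
small-sample degrees of freedom (m−1)(1 + W̄/((1+1/m)B))²; when B = 0
the interval reduces to the single-dataset normal interval. Default
predictors: age, sex, APACHE II, PaO2:FiO2, arm, ICU days. EQ-5D is not
imputed (wave means already pool all available questionnaires).

## Reporting

Rates are percentages to 1 dp: in-hospital mortality counts deaths at or
before hospital discharge over all randomised; the one-year rate adds
later deaths to day 365; response rates divide returned questionnaires
by survivors alive at the wave. Cost tables give mean, normal-based 95 %
CI, median and quartiles (the normal CI matches the "mean (95 % CI)"
presentation; cost data are skewed, so a bootstrap option exists);
singleton groups are flagged rather than given a degenerate CI. Subgroup
cut-points: age 65, APACHE II 26 (22 selectable), PaO2:FiO2 15 kPa, ICU
stay 15 days. Cost per one-year survivor is the summed societal cost of
*all* patients divided by the number alive at one year — the stated
definition, which differs from published rounded-mean arithmetic in the
third significant figure. The ICER is ΔC/ΔQ between arms with explicit
dominance handling and an explicit undefined condition at ΔQ = 0.
Baseline comparisons use Welch t and chi-squared with no
multiple-testing correction. `run_pipeline` chains all stages
deterministically from one seed and writes tables, a JSON summary and a
run log.

## Problem sizes and tolerances

Default analysis runs use the trial's n = 795 with 1,000 bootstrap
resamples. Calibration checks use n = 10,000 for the headline QALY
(Monte-Carlo SE ≈ 0.003) and 20 replicates of n = 795 for generator
moments (2-SE bands). The imputation calibration study uses 500
replicates of n = 150 with ~30 % MAR missingness; the bootstrap coverage
study uses 500 cohorts of n = 200 with 250 resamples each. Floating
tolerances in tests are machine-precision (1e-12) for algebraic
identities and sampling-error bands for stochastic quantities.

## Known limitations

* Marginals, not joints: subgroup cost contrasts (e.g. by APACHE band)
  are null in synthetic data by construction.
* The unit-cost table is illustrative; absolute cost levels are
  demonstration values, though their relative structure is anchored
  where the study prints one.
* The 6-month response-rate denominator in the study (survivors alive at
  6 months) is not printed; the generator's 41.1 % base non-response at
  6 months assumes that denominator definition.
* No discounting (one-year horizon), no extrapolation beyond day 365,
  no per-patient QALY accounting of individual discharge dates.
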