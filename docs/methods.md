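# Methods

## Scoring models

### Chilean warning-label score

Each FFQ item carries a per-100 g/ml nutrient profile. An item that is a
pre-packaged processed/ultra-processed product or an added fat
(`packaged_eligible`) receives one "High in" label for every critical
component at or above its cutoff; other items never carry labels. The
shipped cutoffs are the final-phase (2019) values of the Chilean
regulation — solids per 100 g: 275 kcal, 10 g sugars, 4 g saturated fat,
400 mg sodium; liquids per 100 ml: 70 kcal, 5 g, 3 g, 100 mg — stored in
`configs/warning_thresholds.json`, never hard-coded, so alternative
revisions can be substituted. The comparison rule defaults to inclusive
(content ≥ cutoff triggers the label), matching the regulation's
"equal to or greater" framing; a strict rule is available by config.
Dairy items are compared on added sugars only (lactose exempt), which is
why `added_sugars_g` is mandatory for dairy items and defaults to total
sugars otherwise. Liquids are carried in grams with density fixed at
exactly 1 g/ml.

The participant-level score is Σᵢ WSᵢ·Iᵢ/100 per day, with Iᵢ the daily
intake in grams. It is linear (degree-1 homogeneous) in intake and
monotone in both intake and label counts; the test suite asserts both.

Composite FFQ items ("sausages" standing for several cold cuts) are
profiled by `aggregate_constituents`: the unweighted arithmetic mean of
the members' nutrient vectors, eligibility inherited from any member.

### FSAm-NPS

Component cutoff lists are the published FSA/FSAm-NPS tables
(`configs/fsam_points.json`): energy (kJ) 335…3350, sugars 4.5…45 g,
saturated fat 1…10 g, sodium 90…900 mg (10 points each); fibre (AOAC)
0.9…4.7 g and protein 1.6…8.0 g (5 points each); fruit/vegetable/
legume/nut percentage on the non-uniform scale >40→1, >60→2, >80→5.
Points are awarded per cutoff strictly exceeded, so the food score ranges
over [−15, +40] exactly (saturating constructions hit both endpoints —
an acceptance check). The official exception rule (protein points
withheld when the negative subtotal reaches 11 unless the
fruit/vegetable component is at its maximum) is implemented behind a
flag, default off: the plain N − P subtraction is the primary behaviour
and both paths are tested. The energy component is evaluated in kJ
(kcal × 4.184); the individual-level energy weighting uses kcal, the
FFQ's native unit.

### Mediterranean-diet score

The 0–9 adherence score (+1 per beneficial component at/above the
sex-specific median: vegetables, fruits+nuts, legumes, cereals, fish,
fat-quality ratio; +1 per detrimental component below the median: meat,
dairy; +1 for moderate alcohol, 10–50 g/day for men, 5–25 for women) is
used as an imputation predictor and covariate. Because the food model
does not carry monounsaturated fat, the fat-quality component is a
configurable group ratio, by default olive-oil intake over animal-fat
intake — a proxy for the classical MUFA:SFA ratio; it enters only
through median dichotomisation, so only its ranking matters.

## Survival model

`MortalityCoxModel` is a proportional-hazards model with attained age as
the analysis time: origin at birth, delayed entry (left truncation) at
the age the baseline questionnaire was returned, exit at death or
censoring. All data are expressed as (start, stop] age intervals and
fitted with the Efron tie approximation (lifelines
`CoxTimeVaryingFitter`), which makes single-record and repeated-measures
analyses one code path. Fits are stratified by entry-age decile ×
recruitment period (calendar entry year binned into 5 quantile groups by
default); both stratifications are computed on the analysis sample.

The fully adjusted covariate set (26 parameters including the three
quartile indicators) comprises sex, marital status, physical activity
(METs-h/wk), alcohol (g/day), smoking status indicators, pack-years,
snacking, special diet, BMI (centred linear + quadratic), total-energy
quartile indicators, university education years, family history of
CVD/cancer, and prevalent CVD/hypertension/diabetes/cancer/depression/
hypercholesterolaemia.

- **Cause-specific outcomes** drop (not censor) participants who died of
  other causes before fitting.
- **Quartile classification** uses sample quartiles with left-open/
  right-closed intervals above Q1: a value exactly at a cut-point falls
  in the lower quartile.
- **Trend test**: each participant-interval is assigned the median score
  of its quartile and the Wald p of that single continuous regressor is
  reported (ties across quartile medians are allowed).
- **Repeated measures**: participants followed beyond 10 years contribute
  a second interval carrying the cumulative average of baseline and
  10-year scores; smoking, total energy and alcohol are the only
  covariates updated at the split (the update set is deliberately
  minimal). Quartiles for interval exposures are classified on the
  interval-level exposure distribution. Person-time is conserved exactly
  through every split and filter; the suite asserts this.
- **Information criteria**: AIC = −2 logL + 2k; BIC = −2 logL + k ln n
  with n = number of participants (not events). These identities are
  recomputed from the stored logL/k/n for every fit.

### Exclusions and imputation

Implausible energy reporters are dropped by one of three rules: outside
the sample 1st–99th percentiles (default), outside the 5th–95th, or the
Willett fixed limits (men outside 800–4000 kcal/day, women 500–3500).
Missing pack-years (the only covariate allowed to be missing) are singly
imputed by a deterministic least-squares fit on age, sex, physical
activity, education, BMI, alcohol, MedDiet adherence and vital status,
with predictions floored at zero; observed values are never touched, and
more than 50% missingness is refused.

### Splines, subgroups, combined exposures

Dose-response curves use a 3-knot restricted cubic spline (Harrell
basis, linear beyond the boundary knots; knots at the 10th/50th/90th
exposure percentiles), normalised to HR = 1 at score 0; if the exposure
has no support near zero the reference shifts to the observed minimum
with a warning. Pointwise 95% bands come from the delta method on the
two-dimensional coefficient; the non-linearity p is the LRT of the
non-linear term (df 1).

The subgroup suite splits by sex, age at recruitment (<45/≥45), BMI
(<25/≥25) and ever-smoking, re-classifying quartiles within each stratum;
heterogeneity is tested by the LRT of quartile × group product terms
(df 3). When the group indicator is linearly spanned by existing
covariates (the ever-smoking split alongside smoking-status indicators)
the main effect is dropped and the LRT compares the same base model with
and without the product terms. Sensitivity scenarios: alternative energy
limits, prevalent-condition exclusion, premature-death exclusion (events
within 2 years of entry removed entirely), dropping the snacking
adjustment, adding fibre adjustment. Scenarios that lose all events are
skipped with a warning rather than failing the suite.

Combined-exposure analyses cross-classify two scores at their medians
(value at the median counts as "high"), fit the three non-reference
cells against the both-low reference, and test interaction by the LRT of
the product cell against the two-main-effects model (df 1). Empty cells
are an error naming the cell.

Leave-one-label-out re-scores the cohort four times with one label type
removed from WS counting, re-classifies quartiles and refits; removal can
only lower scores (asserted participant-wise).

## Synthetic cohort generator

The generator emulates the structure the analyses assume — it is the
package's test bed, not a model of any real population.

- **Foods**: 136 items in 34 groups (fresh produce, meats, fish, dairy,
  breads/cereals, fats, pastries, snacks, beverages, ready meals, …),
  nutrients drawn log-normally (σ_log = 0.18) around group-typical
  per-100 g values; processed/ultra-processed groups and added fats are
  label-eligible, fresh groups are not; the eligible fraction is matched
  to its configured value (default 0.47) by toggling designated swing
  items. Liquids carry density 1.
- **FFQ responses**: each participant has a log-normal appetite
  (σ = 0.25) and a standard-normal "unhealthy diet" trait loading
  positively (+0.35) on unhealthy groups and negatively (−0.15) on
  healthy ones; item-level log-normal noise (σ = 0.5) is added and the
  implied servings/day are snapped to the nearest of the nine FFQ
  categories in log space.
- **Calibration** is deterministic and runs once per seed: eligible-item
  base rates are scaled so a neutral participant's warning score equals
  the target median (7.1/day, the published cut); the remaining rates are
  scaled toward a mean energy of 2,500 kcal/day using the analytic
  log-normal mean factors. The resulting quartile cut-points land near
  the published set (≈5.3/7.1/9.6 vs 5.0/7.1/9.8), energy ≈2,540 ± 760
  kcal/day with the expected gradient across score quartiles.
- **Covariates**: age ~ N(38, 12.4²) truncated to [20, 75] and negatively
  correlated with the diet trait; 39% men (trait-linked); smoking,
  BMI ~ N(23.5, 3.5²), physical activity, marital status, education,
  snacking, special diet, prevalence flags and family history with
  plausible marginals and trait/age links; entry year Beta(1.2, 1.6) over
  1999–2017 (median follow-up ≈12.3 y to the administrative end).
  Pack-years are built from age and a log-normal intensity for ever
  smokers. Ultra-processed servings/day are summed from the UPF groups
  and provided as a column.
- **Outcomes**: piecewise-constant baseline hazard on 5-year age bands
  rising at 0.085/log-year, multiplied by exp(cause-specific quartile
  log-HR + covariate effects), with baseline cause shares
  51.8/19.3/26.1/2.8% (cancer/CVD/other/unknown). Default injected
  quartile profiles are cancer (1.14, 1.50, 1.91) and CVD
  (0.87, 0.77, 1.20), null for other causes; covariate log-HRs are
  modest literature-plausible values (male 0.45, current smoking 0.80,
  former 0.25, BMI 0.03/unit) and are generator config, not estimates.
  The overall hazard scale is found by bisection on the expected-event
  equation against the 2.3% target (no resampling); event times come
  from exact inversion of the piecewise cumulative hazard. 7% of
  participants are lost to follow-up at a uniform time.
- **Repeat FFQ**: latent traits are autocorrelated by a factor solved in
  two steps against an internal same-latent replicate so the induced
  baseline-vs-10-year warning-score Pearson correlation hits its target
  (default 0.37 ± 0.05 at n = 20,000). ρ = 1 returns the baseline
  responses unchanged; ρ = 0 gives near-zero correlation.
- **Missingness**: pack-years are masked MAR at 7.9% overall, with former
  smokers twice and never smokers 0.7 times the base odds, exercising the
  imputer under its intended mechanism.

What the generator does **not** emulate: real food-composition values,
correlated nutrient measurement error, FFQ recall bias, differential
loss to follow-up, competing-risk dependence beyond shared covariates,
or the joint covariate distribution of any real cohort. Passing
recovery tests therefore demonstrates that the pipeline estimates what
it claims under its own assumptions — not that those assumptions hold in
any particular study population.

## Numerical choices and problem sizes

- Quartile boundaries: value ≤ cut → lower interval (exact arithmetic on
  the sample quartiles from `numpy.quantile`, linear interpolation).
- Cox convergence failures and singular information matrices surface as
  `FitError` with the engine's diagnostic; the subgroup suite downgrades
  them to warnings and skips the scenario.
- The null-calibration property (type-I error of the Q4 Wald test ≈5%,
  CI coverage at nominal level, uniform trend p) runs 500 replicates of
  n = 250 cohorts with an elevated event fraction so the whole loop stays
  inside a routine test run; parameter-recovery checks run at the full
  n = 20,000 with replicate counts chosen for the suite's runtime (8 and
  6), while `scripts/acceptance.py` runs 40 replicates per outcome.
  Recovery fits adjust for the generator's true hazard confounders (sex,
  smoking, BMI; age through the timescale and strata) — the correctly
  specified estimator for the injected truth — rather than the full
  26-parameter set, which at ~10 events per parameter adds a measurable
  away-from-null sparse-data bias (see Known limitations). Monte-Carlo
  tolerances in tests are 3× the replicate-mean standard error with a
  floor at the documented recovery tolerance.
- Seeds: every random quantity flows from one `numpy` Generator seeded by
  `GeneratorConfig.seed`; the acceptance script derives per-replicate
  seeds from a `SeedSequence` of its `--seed`.

## Known limitations

- With ~230 cause-specific events against 26 parameters, the partial-MLE
  carries an away-from-null sparse-data bias of a few percent on the log
  hazard ratio (recovered cancer hazard ratios average ~2.0 against an
  injected 1.91 under the full adjustment set); the all-cause fit
  (~450 events) is essentially unbiased. Recovery checks therefore use
  the correctly specified lean adjustment; analyses of the full
  multivariable model should read cause-specific estimates with this in
  mind.
- Single (not multiple) imputation understates covariate uncertainty by
  design; competing risks are handled by exclusion, not by Fine–Gray
  models; both mirror the analysis plan the package implements.
- The spline reference at score 0 extrapolates below the observed
  minimum score when the cohort consumes some labelled food everywhere;
  the shifted-reference warning marks this.
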