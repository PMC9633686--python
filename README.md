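# foplabel

Front-of-pack (FoP) nutrient-profile scoring and cohort mortality analysis
for food-frequency-questionnaire (FFQ) data.

Two FoP labelling systems are implemented at food and individual level:

- **Chilean warning-label score.** A pre-packaged product carries one black
  "High in" octagon for each critical component — energy, sugars, saturated
  fat, sodium — at or above the regulatory cutoff per 100 g (solids) or
  100 ml (liquids), so each product has a label count WS ∈ {0, …, 4}. For
  dairy products only added sugars count (lactose is exempt). The
  individual daily score is

  score = Σᵢ WSᵢ · Iᵢ / 100,

  where Iᵢ is the participant's daily intake of item *i* in grams.

- **FSAm-NPS (the algorithm behind Nutri-Score).** Per 100 g/ml a food
  accrues 0–10 "negative" points each for energy (kJ), sugars, saturated
  fat and sodium, and 0–5 "positive" points each for fibre, protein and the
  fruit/vegetable/legume/nut percentage; the food score N − P ranges from
  −15 (healthiest) to +40. The individual score is the energy-weighted
  mean over all foods consumed.

The survival side is a statsmodels-style model/results pair:
`MortalityCoxModel` fits a proportional-hazards model with **attained age
as the analysis time** (birth as origin, delayed entry at the age the
baseline questionnaire was returned), stratified by age decile ×
recruitment period, with the usual epidemiological adjustment set
(smoking, BMI linear + quadratic, total-energy quartiles, …).
`MortalityCoxResults` carries hazard ratios per score quartile (Q1
reference), Wald CIs, the trend test across quartile medians, the log
partial likelihood and AIC/BIC (BIC with n = participants). On top of the
pair sit the quartile trend test, subgroup/sensitivity suites,
leave-one-label-out re-scoring, restricted-cubic-spline dose-response
curves (3 knots, HR referenced to score 0), combined-exposure
cross-classification and AIC/BIC model comparison.

Because cohort FFQ microdata are rarely shareable, the package includes a
seeded synthetic-cohort generator (`foplabel.simulate`) that emulates a
136-item FFQ cohort of ~20,000 adults followed ~12 years for cause-specific
mortality, with injectable quartile log-hazards, a 10-year repeat FFQ with
configurable score autocorrelation, and missing-at-random pack-years. Every
pipeline stage is therefore testable end-to-end against known truths.

## Worked example

```python
from foplabel import CohortSimulator, GeneratorConfig
from foplabel.cohort import analyze_cohort

bundle = CohortSimulator(GeneratorConfig(n=20_000, seed=1)).run(with_followup=False)
res, df = analyze_cohort(bundle["records"], with_trend=True)
print(res.summary())
```

```
Proportional-hazards fit (age timescale, delayed entry)
  outcome: all_cause   tag: multivariable-all_cause
  participants: 19600   events: 421   person-years: 235893
  log partial likelihood: -2218.12   k: 26
  AIC: 4488.2   BIC: 4693.2
  p-trend: 0.008028

  parameter                   HR              95% CI         p
  q2                       1.521       (1.122-2.062)   0.00687
  q3                       1.625       (1.127-2.342)   0.00924
  q4                       1.929       (1.244-2.991)   0.00332
  male                     1.368       (1.127-1.661)   0.00155
  ...
```

Reading the output: 20,000 simulated participants lose 2% to the
extreme-energy exclusion (outside the 1st–99th total-energy percentiles),
leaving 19,600 with 421 deaths over ~236k person-years. The score quartile
cut-points for this seed are 5.3 / 7.1 / 9.6 per day. The default
generator injects harmful cause-specific quartile effects (cancer Q4 log-HR
ln 1.91, CVD ln 1.20), so the fitted Q4-vs-Q1 hazard ratio — 1.93
(1.24–2.99) for this single seed — scatters around the implied all-cause
truth of ≈1.5 from replicate to replicate; the acceptance script below
averages replicates to show the recovery. The trend p of 0.008 reflects the
monotone dose-response across quartiles.

The same chain is available from a shell:

```sh
foplabel simulate --seed 1 --n 20000 --outdir scratch/run1
foplabel score --foods scratch/run1/foods.csv --ffq scratch/run1/ffq_baseline.csv \
         --outdir scratch/run1/scores
foplabel fit --bundle scratch/run1 --outdir scratch/run1/fit
foplabel report --fitdir scratch/run1/fit
```

Every run writes a `manifest.json` (seed, config hash, input digests,
output inventory) so results are replayable.

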