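{
  "version": "midpoint-default",
  "categories": [
    "never",
    "1-3/month",
    "1/week",
    "2-4/week",
    "5-6/week",
    "1/day",
    "2-3/day",
    "4-6/day",
    ">6/day"
  ],
  "servings_per_day": [
    0.0,
    0.06666666666666667,
    0.14285714285714285,
    0.42857142857142855,
    0.7857142857142857,
    1.0,
    2.5,
    5.0,
    7.0
  ]
}
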