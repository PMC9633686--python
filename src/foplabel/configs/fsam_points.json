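{
  "version": "fsam-nps-2015",
  "exception_rule": false,
  "negative": {
    "energy_kj": [335, 670, 1005, 1340, 1675, 2010, 2345, 2680, 3015, 3350],
    "sugars_g": [4.5, 9, 13.5, 18, 22.5, 27, 31, 36, 40, 45],
    "sat_fat_g": [1, 2, 3, 4, 5, 6, 7, 8, 9, 10],
    "sodium_mg": [90, 180, 270, 360, 450, 540, 630, 720, 810, 900]
  },
  "positive": {
    "fibre_g": {"cutoffs": [0.9, 1.9, 2.8, 3.7, 4.7]},
    "protein_g": {"cutoffs": [1.6, 3.2, 4.8, 6.4, 8.0]},
    "fvnl_pct": {"cutoffs": [40, 60, 80], "points": [1, 2, 5]}
  }
}
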