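{
  "version": "chile-2019-final-phase",
  "rule": "inclusive",
  "solid": {
    "energy_kcal": 275.0,
    "sugars_g": 10.0,
    "sat_fat_g": 4.0,
    "sodium_mg": 400.0
  },
  "liquid": {
    "energy_kcal": 70.0,
    "sugars_g": 5.0,
    "sat_fat_g": 3.0,
    "sodium_mg": 100.0
  }
}
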