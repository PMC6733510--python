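{
  "diltiazem_I": {
    "compound": "Diltiazem",
    "provenance": "Diltiazem I",
    "primary": {"target": "gCaL", "ic50_uM": 0.76, "hill_slope": 1.14},
    "off_targets": [
      {"target": "gKr", "ic50_uM": 13.2, "hill_slope": 1.16},
      {"target": "gNa", "ic50_uM": 22.4, "hill_slope": 1.29}
    ],
    "primary_fraction_grid": [0.05, 0.1, 0.5, 0.9]
  },
  "moxifloxacin_II": {
    "compound": "Moxifloxacin",
    "provenance": "Moxifloxacin II",
    "primary": {"target": "gKr", "ic50_uM": 86.2, "hill_slope": 0.94},
    "off_targets": [
      {"target": "gCaL", "ic50_uM": 173.0, "hill_slope": 1.0},
      {"target": "gNa", "ic50_uM": 1112.0, "hill_slope": 1.0}
    ],
    "primary_fraction_grid": [0.25, 0.5, 0.9, 0.95]
  },
  "moxifloxacin_III": {
    "compound": "Moxifloxacin",
    "provenance": "Moxifloxacin III",
    "primary": {"target": "gKr", "ic50_uM": 93.041, "hill_slope": 0.6},
    "off_targets": [
      {"target": "gNaL", "ic50_uM": 382.337, "hill_slope": 1.1},
      {"target": "gKs", "ic50_uM": 50.321, "hill_slope": 1.0}
    ],
    "concentration_grid_uM": [277.4, 86.2, 8.32, 3.76]
  },
  "ivabradine": {
    "compound": "Ivabradine",
    "provenance": "gf scaling only; incremental incubation, no concentration-effect relation",
    "gf_scaling_only": true,
    "direction": "inhibition"
  },
  "forskolin": {
    "compound": "Forskolin",
    "provenance": "gf scaling only; indirect If activator, no concentration-effect relation",
    "gf_scaling_only": true,
    "direction": "augmentation"
  }
}
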