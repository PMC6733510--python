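{
  "provenance": "surrogate",
  "note": "SYNTHETIC reference curves. The experimental second-order polynomial fits of repolarization duration vs inter-beat interval (and their 90% prediction bands) are not printed in any source available to this package; these coefficients are plausible stand-ins for iCell monolayer data and must never be quoted as experimental values.",
  "model": "repolarization_s = c0 + c1*rr_s + c2*rr_s^2, band = +/- halfwidth",
  "curves": {
    "rate_modulation": {
      "coefficients": [0.151, 0.18, -0.02],
      "band_halfwidth_s": 0.035,
      "rr_range_s": [0.8, 3.5]
    },
    "repolarization_block": {
      "coefficients": [0.1, 0.22, -0.025],
      "band_halfwidth_s": 0.04,
      "rr_range_s": [1.0, 3.0]
    }
  }
}
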