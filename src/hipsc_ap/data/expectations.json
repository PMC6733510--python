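{
  "note": "Qualitative experimental directions of rr and repolarization duration in iCell monolayers for each intervention family, as reported for the reference compounds. Kept as data because the study's point is precisely where model and experiment disagree.",
  "if_inhibition": {"compound": "Ivabradine", "rr": "up", "repolarization": "up"},
  "if_augmentation": {"compound": "Forskolin", "rr": "down", "repolarization": "down"},
  "ical_block": {"compound": "Diltiazem", "rr": "down", "repolarization": "down"},
  "ikr_block": {"compound": "Moxifloxacin", "rr": "up", "repolarization": "up"}
}
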