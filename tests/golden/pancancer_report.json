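{
  "cohorts": [
    "COHORT1",
    "COHORT2",
    "COHORT3"
  ],
  "config_hash": "02ad46bda48c9c55",
  "n_abundant_isomirs": 36,
  "n_adjacent_pairs": 7,
  "n_universal_edges": 47
}
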