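{
  "gene": "LWS",
  "numbering_reference": "LWS_numbering_scaffold",
  "base_lambda_max": 560.0,
  "base_genotype": {"180": "S", "197": "H", "277": "Y", "285": "T", "308": "A"},
  "shifts": {
    "180:S>A": -5.0,
    "197:H>Y": -28.0,
    "277:Y>F": -8.0,
    "285:T>A": -15.0,
    "308:A>S": -27.0
  },
  "notes": "Additive single-substitution lambda-max shifts for the five LWS tuning sites, after Yokoyama and colleagues' five-site rule (range 510-560 nm). The S180A magnitude (-5 nm) is anchored to the 560/555 nm base-genotype pair used by this table."
}
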