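{
  "gene_roles": {
    "BMG001": "risk",
    "BMG002": "null",
    "BMG003": "novel_multi",
    "BMG004": "novel_single",
    "BMG005": "decoy_gnomad",
    "BMG006": "decoy_unaff_hom"
  },
  "penetrance_expected": {
    "BMG003": true,
    "BMG004": true,
    "BMG005": false,
    "BMG006": false
  },
  "phase": [
    {
      "phase": "trans",
      "sample": "S00001",
      "variant_a": "1:3599:A:T",
      "variant_b": "1:3838:A:T"
    },
    {
      "phase": "cis",
      "sample": "S00002",
      "variant_a": "1:3599:A:T",
      "variant_b": "1:3838:A:T"
    }
  ],
  "tiers": {
    "BMG001": "high",
    "BMG002": "moderate_low",
    "BMG003": "none",
    "BMG004": "none",
    "BMG005": "none",
    "BMG006": "none"
  },
  "true_or": {
    "BMG001": 5.0,
    "BMG002": 1.0,
    "BMG003": 1.0,
    "BMG004": 1.0,
    "BMG005": 1.0,
    "BMG006": 1.0
  }
}
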