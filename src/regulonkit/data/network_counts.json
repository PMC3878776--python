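{
  "psu_network": {
    "total": 308,
    "enzymes": 174,
    "uptake": 65,
    "regulators": 32,
    "undefined": 37
  },
  "novel_genes": {
    "total": 173,
    "enzymes": 82,
    "transporters": 22,
    "transcription_factors": 32,
    "undefined": 37
  },
  "model_seed_overlap": {
    "total": 68,
    "enzymes": 63,
    "transporters": 5
  },
  "curated_model_overlap": {
    "total": 125,
    "enzymes": 84,
    "transporters": 41
  }
}
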