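{
  "name": "GF-6",
  "bands": [
    {"name": "Blue", "shape": "boxcar", "lower": 450, "upper": 520},
    {"name": "Green", "shape": "boxcar", "lower": 520, "upper": 590},
    {"name": "Red", "shape": "boxcar", "lower": 630, "upper": 690},
    {"name": "NIR", "shape": "boxcar", "lower": 770, "upper": 890},
    {"name": "RE1", "shape": "boxcar", "lower": 690, "upper": 730},
    {"name": "RE2", "shape": "boxcar", "lower": 730, "upper": 770},
    {"name": "PE", "shape": "boxcar", "lower": 400, "upper": 450},
    {"name": "YE", "shape": "boxcar", "lower": 590, "upper": 630}
  ]
}
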