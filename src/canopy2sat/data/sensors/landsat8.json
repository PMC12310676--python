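{
  "name": "Landsat-8",
  "bands": [
    {"name": "Coastal", "shape": "boxcar", "lower": 433, "upper": 453},
    {"name": "Blue", "shape": "boxcar", "lower": 450, "upper": 515},
    {"name": "Green", "shape": "boxcar", "lower": 525, "upper": 600},
    {"name": "Red", "shape": "boxcar", "lower": 630, "upper": 680},
    {"name": "NIR", "shape": "boxcar", "lower": 845, "upper": 885},
    {"name": "SWIR1", "shape": "boxcar", "lower": 1560, "upper": 1660},
    {"name": "SWIR2", "shape": "boxcar", "lower": 2100, "upper": 2300},
    {"name": "Cirrus", "shape": "boxcar", "lower": 1360, "upper": 1390}
  ]
}
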