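{
  "name": "Sentinel-2",
  "comment": "Centers follow the MSI band table; only centers are published in the source band list, so response curves are synthesized as gaussians. FWHM values are editable defaults: 15 nm for the red-edge bands, nominal MSI bandwidths elsewhere.",
  "bands": [
    {"name": "Coastal", "shape": "gaussian", "center": 443, "fwhm": 20},
    {"name": "Blue", "shape": "gaussian", "center": 490, "fwhm": 65},
    {"name": "Green", "shape": "gaussian", "center": 560, "fwhm": 35},
    {"name": "Red", "shape": "gaussian", "center": 665, "fwhm": 30},
    {"name": "RE1", "shape": "gaussian", "center": 705, "fwhm": 15},
    {"name": "RE2", "shape": "gaussian", "center": 740, "fwhm": 15},
    {"name": "RE3", "shape": "gaussian", "center": 783, "fwhm": 20},
    {"name": "NIR1", "shape": "gaussian", "center": 842, "fwhm": 115},
    {"name": "NIR2", "shape": "gaussian", "center": 865, "fwhm": 20},
    {"name": "WaterVapor", "shape": "gaussian", "center": 945, "fwhm": 20},
    {"name": "Cirrus", "shape": "gaussian", "center": 1375, "fwhm": 30},
    {"name": "SWIR1", "shape": "gaussian", "center": 1610, "fwhm": 90},
    {"name": "SWIR2", "shape": "gaussian", "center": 2190, "fwhm": 180}
  ]
}
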