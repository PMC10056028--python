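[
  {"name": "caudate_L", "center_mm": [-14.0, 12.0, 8.0], "volume_cm3": 1.5},
  {"name": "caudate_R", "center_mm": [14.0, 12.0, 8.0], "volume_cm3": 1.5},
  {"name": "anterior_putamen_L", "center_mm": [-26.0, 10.0, -6.0], "volume_cm3": 1.5},
  {"name": "anterior_putamen_R", "center_mm": [26.0, 10.0, -6.0], "volume_cm3": 1.5},
  {"name": "posterior_putamen_L", "center_mm": [-28.0, -12.0, -4.0], "volume_cm3": 1.5},
  {"name": "posterior_putamen_R", "center_mm": [28.0, -12.0, -4.0], "volume_cm3": 1.5},
  {"name": "occipital_L", "center_mm": [-25.0, -75.0, 0.0], "volume_cm3": 1.5},
  {"name": "occipital_R", "center_mm": [25.0, -75.0, 0.0], "volume_cm3": 1.5},
  {"name": "pineal", "center_mm": [0.0, -30.0, 6.0], "volume_cm3": 1.5},
  {"name": "background", "center_mm": [0.0, 45.0, 25.0], "volume_cm3": 1.5}
]
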