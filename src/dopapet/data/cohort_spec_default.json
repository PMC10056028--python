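{
  "n_nsd": 69,
  "n_non_nsd": 43,
  "pineal_log_mean_nsd": -0.104,
  "pineal_log_mean_non_nsd": -0.3665,
  "pineal_log_sd": 0.3,
  "occipital_log_mean": -0.673,
  "occipital_log_sd": 0.15,
  "shared_log_sd": 0.3,
  "occ_asymmetry": 0.05,
  "va_bg_sensitivity": 0.8840579710144928,
  "va_bg_specificity": 0.9302325581395349,
  "equivocal_rate": 0.0,
  "seed": 0
}
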