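# NSAID-like null profile: no detectable effect on sleep architecture.
effects:
  - onset_zt: 2.0
    duration_h: 4.0
    wake_propensity_mult: 1.0
    wake_mean_mult: 1.0
    nrem_mean_mult: 1.0
    rem_mean_mult: 1.0
    latency_delay_min: 0.0
    label: meloxicam_null
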