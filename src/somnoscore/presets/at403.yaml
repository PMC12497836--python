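# NOP-agonist-like profile: NREM promotion with REM suppression and reduced
# sleep latency, lasting ~6 h after a ZT2 dose.
effects:
  - onset_zt: 2.0
    duration_h: 6.0
    wake_propensity_mult: 0.3
    wake_mean_mult: 0.4
    nrem_mean_mult: 1.8
    rem_mean_mult: 0.3
    latency_delay_min: 0.0
    label: at403
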