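# Mu-opioid-like profile: NREM and REM suppression with markedly increased
# sleep latency for ~4 h after a ZT2 dose.
effects:
  - onset_zt: 2.0
    duration_h: 4.0
    wake_propensity_mult: 2.5
    wake_mean_mult: 2.0
    nrem_mean_mult: 0.5
    rem_mean_mult: 0.25
    latency_delay_min: 45.0
    label: morphine
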