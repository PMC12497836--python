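# Transient wake-promoting noxious stimulus (5.6% i.p. lactic acid analogue):
# NREM and REM suppressed for ~1.5 h after a ZT2 injection, with a short
# forced-wake latency delay.
effects:
  - onset_zt: 2.0
    duration_h: 1.5
    wake_propensity_mult: 2.0
    wake_mean_mult: 1.3
    nrem_mean_mult: 0.6
    rem_mean_mult: 0.4
    latency_delay_min: 12.0
    label: lactic_acid_5p6
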