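# Published Poisson saturation estimates per series selection, used by
# `satscreen reproduce`. Selections: WT = EMS/WT + ENU/WT; ALL = all six
# series. deviation=true marks the combined-series lambda display, whose
# published value (9.0) disagrees with the rounding of 118/13 = 9.08.
selection	published_lambda	published_P0	published_N0	lambda_deviation
WT	7.0	0.0009	0.009	false
EMS/WT	5.6	0.0036	0.029	false
ENU/WT	3.6	0.0281	0.202	false
ALL	9.0	0.0001	0.001	true
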