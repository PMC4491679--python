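organ,soc_max,soc_mean,mlc_rc_max,mlc_rc_mean,mlc_only_max,mlc_only_mean
Anterior Rectal Wall,76.77,39.48,76.89,75.90,76.89,75.90
Bladder,77.09,12.87,76.35,12.18,76.35,12.06
CTV,77.63,75.90,76.89,75.90,76.89,75.90
Distal Seminal Vesicles,75.37,67.63,75.87,68.74,75.80,68.29
Femoral Heads,36.94,25.28,42.16,25.38,42.15,25.30
Proximal Seminal Vesicles,76.92,75.83,76.46,75.85,76.45,75.83
Rectum,76.81,16.73,76.34,16.81,76.33,16.76
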