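organ,external_mSv,internal_mSv,total_mSv
Anterior Rectal Wall,174,641,815
Bladder,170,413,582
CTV,172,938,1110
Distal Seminal Vesicles,173,787,960
Femoral Heads,217,572,789
Prostate,173,941,1113
Proximal Seminal Vesicles,169,873,1042
Rectum,171,481,652
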