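organ,external_mSv,internal_mSv,total_mSv
Anterior Rectal Wall,228,561,788
Bladder,222,363,585
CTV,228,840,1067
Distal Seminal Vesicles,233,691,924
Femoral Heads,280,531,811
Prostate,227,841,1068
Proximal Seminal Vesicles,239,814,1053
Rectum,223,425,648
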