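label,mean_mm,se_mm,n
study_1,1.97,0.003,3918
study_2,1.88,0.023,118
study_3,1.88,0.009,475
study_4,1.98,0.036,62
study_5,1.82,0.015,110
study_6,1.96,0.018,122
study_7,1.97,0.031,88
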