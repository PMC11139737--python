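subject,gender,age_y,weight_kg,height_m,activity_rest_MBq,activity_stress_MBq
P1,F,57,57,1.65,407.00,407.03
P2,M,29,88,1.96,404.59,409.19
P3,M,40,84,1.72,398.43,401.73
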