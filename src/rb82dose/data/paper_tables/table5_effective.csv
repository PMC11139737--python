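quantity,icrp128,p1_rest,p1_stress,p2_rest,p2_stress,p3_rest,p3_stress
Effective dose,1.1,0.757,0.745,0.502,0.553,0.593,0.597
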