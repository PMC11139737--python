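organ,w_T
red_marrow,0.12
colon,0.12
lung,0.12
stomach_wall,0.12
breasts,0.12
gonads,0.08
urinary_bladder_wall,0.04
esophagus,0.04
liver,0.04
thyroid,0.04
bone_surface,0.01
brain,0.01
salivary_glands,0.01
skin,0.01
remainder,0.12
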