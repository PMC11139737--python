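target_organ,p1_rest,p1_stress,p2_rest,p2_stress,p3_rest,p3_stress
Adrenals,1.49,1.98,0.989,1.03,1.02,1.05
Gallbladder content,0.574,0.860,0.350,0.412,0.555,0.995
Stomach content,1.38,1.84,0.652,0.776,0.742,0.965
Heart content,2.74,3.08,1.67,1.57,1.37,1.80
Heart wall,2.47,3.92,1.57,1.96,1.59,1.86
Kidneys,4.56,4.87,3.22,3.24,5.37,4.52
Liver,0.907,1.16,0.512,0.710,0.954,1.25
Lungs,1.72,1.92,1.25,1.15,1.11,0.985
Spleen,2.11,2.51,1.22,1.24,1.33,1.20
Thyroid,1.87,2.01,1.03,1.14,0.418,0.370
Urinary bladder content,0.269,0.535,0.111,0.105,0.280,0.306
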