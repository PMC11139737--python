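target_organ,icrp128,p1_rest,p1_stress,p2_rest,p2_stress,p3_rest,p3_stress
Adrenals,2.4,0.758,0.744,0.754,0.786,1.15,1.15
Brain,0.14,0.402,0.401,0.332,0.325,0.315,0.314
Breasts,0.19,0.418,0.417,,,,
Esophagus,1.5,0.524,0.528,0.421,0.422,0.411,0.412
Eyes,,0.402,0.401,0.332,0.325,0.315,0.314
Gallbladder wall,0.72,0.526,0.557,0.461,0.501,0.466,0.516
Heart wall,4.0,2.53,2.78,1.87,2.03,1.84,1.9
Kidneys,9.3,2.97,2.76,3.58,3.59,5.73,5.0
Left colon,,0.491,0.492,0.397,0.395,0.396,0.395
Liver,0.98,0.96,1.14,0.668,0.951,0.891,1.17
Lungs,2.6,1.88,1.68,1.33,1.25,1.15,0.943
Osteogenic cells,,0.267,0.266,0.26,0.256,0.251,0.249
Ovaries,0.5,0.45,0.45,,,,
Pancreas,2.6,0.525,0.534,0.415,0.423,0.424,0.434
Prostate,,,,0.371,0.364,0.356,0.354
Rectum,,0.444,0.444,0.372,0.365,0.355,0.354
Red marrow,0.38,0.357,0.355,0.296,0.293,0.287,0.286
Right colon,,0.469,0.47,0.39,0.389,0.383,0.385
Salivary glands,,0.415,0.414,0.352,0.345,0.334,0.333
Small intestine wall,2.0,0.451,0.451,0.387,0.383,0.378,0.377
Spleen,0.18,1.89,1.76,1.45,1.48,2.3,2.26
Stomach wall,0.83,1.04,1.1,0.436,0.821,0.982,1.23
Testes,0.26,,,0.343,0.336,0.325,0.324
Thymus,1.5,0.652,0.638,0.436,0.435,0.417,0.416
Thyroid,0.31,1.34,1.23,0.881,0.941,1.22,1.06
Total body,0.31,0.524,0.524,0.422,0.423,0.423,0.423
Urinary bladder wall,0.18,0.451,0.493,0.43,0.417,0.388,0.397
Uterus,1.0,0.446,0.446,,,,
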