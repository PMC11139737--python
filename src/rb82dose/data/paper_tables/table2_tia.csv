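source_organ,icrp128,p1_rest,p1_stress,p2_rest,p2_stress,p3_rest,p3_stress
Adrenals,0.000046,0.000003,0.000003,0.000005,0.000005,0.000008,0.000009
Gallbladder content,,0.000005,0.000008,0.000003,0.000004,0.000001,0.000003
Stomach content,,0.000278,0.000311,0.000181,0.000226,0.000320,0.000460
Heart content,0.0013,0.001142,0.001131,0.001117,0.001069,0.001116,0.001076
Heart wall,0.00094,0.000291,0.000378,0.000300,0.000383,0.000290,0.000331
Kidneys,0.0033,0.001008,0.000929,0.001373,0.001376,0.002221,0.001929
Liver,0.0018,0.001318,0.001616,0.001141,0.001722,0.001582,0.002164
Lungs,0.0029,0.002360,0.002086,0.002040,0.001892,0.001723,0.001367
Spleen,0.00062,0.000291,0.000270,0.000257,0.000262,0.000416,0.000409
Thyroid,0.000038,0.000034,0.000031,0.000025,0.000027,0.000036,0.000031
Urinary bladder content,0.000044,0.000017,0.000033,0.000035,0.000032,0.000023,0.000028
Total body,,0.023489,0.023441,0.023760,0.023239,0.022499,0.022431
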