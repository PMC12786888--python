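region,metric,T0,T1,T2
left_cheek,contrast,7.52,6.20,6.20
right_cheek,contrast,7.46,6.16,6.17
nose,contrast,6.86,5.95,5.92
chin,contrast,6.92,5.95,5.73
face,contrast,7.28,6.02,6.03
left_cheek,homogeneity,0.488,0.511,0.510
right_cheek,homogeneity,0.482,0.499,0.506
nose,homogeneity,0.496,0.518,0.518
chin,homogeneity,0.488,0.506,0.510
face,homogeneity,0.490,0.512,0.511
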