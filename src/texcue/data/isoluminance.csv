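# texcue isoluminance fixture v1: observer L:M luminance weight k and Lum:S ratio at isoluminance
observer,k,lum_s_ratio
P1,1.71,0.048
P2,0.99,0.073
P3,1.39,0.084
P4,1.12,0.043
P5,1.18,0.076
P6,1.7,0.07
P7,0.93,0.077
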