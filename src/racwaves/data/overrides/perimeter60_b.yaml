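k1: 0.048
k2: 0.33
k3a: 0.57
k11: 0.006
L: 60.0
N_Rac1: 8100.0
N_GAP: 1380.0
N_DGAP1: 1440.0
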