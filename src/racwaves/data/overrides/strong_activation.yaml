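k1: 0.03
k2: 0.25
k3a: 0.7
k11: 0.0046
k12: 0.0056
N_Rac1: 7300.0
N_GAP: 1600.0
N_DGAP1: 1100.0
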