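k3a: 0.39
k11: 0.003
k12: 0.005
k41: 0.0004
k42: 0.002
N_Rac1: 5400.0
N_GAP: 1440.0
N_DGAP1: 1460.0
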