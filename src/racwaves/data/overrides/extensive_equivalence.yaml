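N_Rac1: 9200.0
N_GAP: 880.0
N_DGAP1: 1500.0
k11: 0.005
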