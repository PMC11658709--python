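k3a: 0.42
L: 60.0
N_Rac1: 8580.0
N_GAP: 2040.0
N_DGAP1: 1320.0
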