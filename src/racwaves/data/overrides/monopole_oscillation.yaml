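k3a: 0.65
N_Rac1: 6000.0
N_DGAP1: 900.0
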