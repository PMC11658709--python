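N_Rac1: 5000.0
N_DGAP1: 800.0
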