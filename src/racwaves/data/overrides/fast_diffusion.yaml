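rho_Dmax: 70.0
Dr: 70.0
Dg: 40.0
Dd: 30.0
k1: 0.0157
k2: 0.72
k3a: 0.71
k11: 0.0066
k12: 0.0079
k5: 0.126
k6a: 0.393
k6b: 0.157
k4: 0.11
k41: 0.22
k42: 0.001
N_Rac1: 6340.0
N_GAP: 1360.0
N_DGAP1: 1530.0
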