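k1: 0.02
k11: 0.004
k12: 0.006
k2: 0.22
k3a: 0.45
k4: 0.24
k41: 0.0008
k42: 0.0036
k5: 0.095
k6a: 0.6
k6b: 0.43
Dr: 30.0
Dg: 8.0
Dd: 12.0
rho_Rmax: 200.0
rho_Dmax: 40.0
L: 40.0
N_Rac1: 5200.0
N_GAP: 1200.0
N_DGAP1: 1600.0
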