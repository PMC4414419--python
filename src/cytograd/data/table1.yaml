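# Published IL-2 parameter set (physical constants as printed; trafficking
# rates are package defaults, see docs/methods.md).  Units as in
# cytograd.params.ModelParams.
D: 10.0
rho: 5.0
L_cell: 5.0
q: 10.0
q_eff: 7200.0
k_on: 111.6
k_off: 0.83
k_d: 0.1
a: 2.0
l_syn: 0.02
R_low: 100.0
R_high: 4000.0
frac_secreting: 0.25
v0_Th: 150.0
v0_Treg: 1000.0
v1_Th: 3000.0
v1_Treg: 8000.0
K: 1000.0
hill_n: 3.0
k_iR: 1.6
k_iC: 2.9
k_rec: 5.0
k_deg: 1.0
d_R: 0.0001
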