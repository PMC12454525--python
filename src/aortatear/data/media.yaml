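# Aortic media: GOH layer constants and interface fracture parameters.
c10_kPa: 16.0
k1_kPa: 901.0
k2: 9.0
kappa: 0.12
theta_deg: 41.6
thickness_mm: 1.5
tn_cr_kPa: 131.0
ts_cr_kPa: 97.0
tt_cr_kPa: 120.0
G_N_per_m: 50.0
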