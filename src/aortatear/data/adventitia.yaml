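# Aortic adventitia: GOH layer constants and interface fracture parameters.
c10_kPa: 13.5
k1_kPa: 370.0
k2: 15.2
kappa: 0.25
theta_deg: 54.8
thickness_mm: 0.5
tn_cr_kPa: 131.0
ts_cr_kPa: 97.0
tt_cr_kPa: 120.0
G_N_per_m: 50.0
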