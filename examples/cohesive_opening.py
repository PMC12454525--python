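"""Drive a cohesive interface point through opening, softening and failure.

Monotonically opens the normal separation of a medial interface point with
the catalogued fracture parameters (t_n_cr = 131 kPa, G = 50 N/m).  The
response is linear up to the critical traction, then softens linearly until
full decohesion; the dissipated energy per unit area at failure equals the
fracture energy G.
"""

import numpy as np

from aortatear import TractionState, damage_update, default_cohesive

params = default_cohesive()
state = TractionState()

t_peak, d_peak = 0.0, 0.0
for dn in np.linspace(0.0, 0.8, 2001):
    state = damage_update(state, (float(dn), 0.0, 0.0), params)
    if state.traction[0] > t_peak:
        t_peak, d_peak = state.traction[0], dn
    if state.failed:
        break

print(f"peak normal traction : {t_peak:.1f} kPa at separation {d_peak:.4f} mm "
      f"(critical value {params.critical_tractions[0]} kPa)")
print(f"full decohesion at   : {state.separation[0]:.3f} mm separation")
print(f"dissipated energy    : {state.dissipated:.2f} N/m "
      f"(fracture energy G = {params.fracture_energy} N/m)")
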