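"""Critical pressure for one predefined medial tear.

Takes the Aorta-1 descending fixture, recovers its zero-load geometry, and
finds the true/false-lumen pressure at which a 6 mm x 6 mm circumferential-
axial (theta-z) tear at the middle of the media starts to propagate: the
pressure where the cohesive initiation ratio at the tear front reaches 1.
"""

from aortatear import (
    TearConfig,
    critical_pressure,
    default_cohesive,
    imaged_vessel_geometry,
    recover_cylinder,
    tear_front_traction,
)

zero_load, _ = recover_cylinder(imaged_vessel_geometry(16.444), image_pressure=80.0)
config = TearConfig("theta_z", extent_theta=6.0, extent_z=6.0, depth=0.75)
cohesive = default_cohesive()

t80 = tear_front_traction(zero_load, config, 80.0, cohesive)
print(f"front traction at the 80 mmHg baseline: t_n = {t80[0]:.1f} kPa, "
      f"t_s = {t80[1]:.1f} kPa (critical t_n = {cohesive.critical_tractions[0]} kPa)")

result = critical_pressure(zero_load, config, cohesive)
print(f"critical pressure : {result.critical_pressure:.1f} mmHg "
      f"(limited by the {result.limiting_component} traction component)")
print("interpretation    : below this lumen pressure the intact interface ahead "
      "of the tear front holds; above it the tear starts to propagate.")
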