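"""How tear depth, tear size and vessel diameter shift the critical pressure.

Sweeps theta-z tears over three medial depths and two sizes on the smallest
(descending, 16.444 mm) and largest (ascending, 41.381 mm) catalogued
fixtures.  The printed table shows the three headline trends: deeper tears
need higher pressures to propagate, larger tears need lower pressures (most
strongly at depth), and tears in larger-diameter vessels propagate at lower
pressures.  Entries at 400 mmHg marked '>' did not initiate inside the
search bracket.
"""

from aortatear import (
    TearConfig,
    critical_pressure,
    default_cohesive,
    imaged_vessel_geometry,
    recover_cylinder,
)

cohesive = default_cohesive()
print(f"{'diameter':>10} {'size (mm)':>10} | " + " ".join(f"d={d:<6}" for d in (0.25, 0.75, 1.25)))
for diameter in (16.444, 41.381):
    zero_load, _ = recover_cylinder(imaged_vessel_geometry(diameter), 80.0)
    for size in (3.0, 12.0):
        row = []
        for depth in (0.25, 0.75, 1.25):
            res = critical_pressure(
                zero_load, TearConfig("theta_z", size, size, depth), cohesive
            )
            row.append((">" if not res.converged else " ") + f"{res.critical_pressure:6.1f}")
        print(f"{diameter:>10.3f} {size:>10.1f} | " + " ".join(row) + "  mmHg")
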