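"""Unit conversions used throughout the package.

Internal unit system: lengths in mm, stresses/stiffnesses in kPa, so that
stress * length = kPa*mm = N/m, which is the natural unit for the interfacial
fracture energy G (1 N/m = 1 J/m^2 = 1 kPa*mm).  Pressures cross module
boundaries in mmHg (the clinical unit) and are converted here.
"""

KPA_PER_MMHG: float = 0.1333224


def mmhg_to_kpa(p_mmhg: float) -> float:
    return p_mmhg * KPA_PER_MMHG


def kpa_to_mmhg(p_kpa: float) -> float:
    return p_kpa / KPA_PER_MMHG
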