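"""Reduced-order tear mechanics: front tractions and critical pressures.

A predefined tear of finite extent sits inside the media of a two-layer
cylinder.  True and false lumen are pressurised equally from the 80 mmHg
diastolic baseline, and the critical pressure is the lumen pressure at which
the cohesive initiation ratio at the tear front first reaches 1.

theta-z tears (normal radial, the propagation-phase geometry)
-------------------------------------------------------------
The tear plane at depth d inside the media splits the wall into an inner
flap (lumen -> tear plane, thickness h_f = d) and an outer shell (remaining
media + adventitia).  Over the torn patch the flap sees equal pressure on
both faces, so its diastolic prestretch is released and it springs back
towards its stress-free radius: the free radial mismatch across the
interface is the prestretch-release displacement

    delta(P) = r_d(P) - R_d

(r_d = loaded, R_d = zero-load tear-plane radius of the intact wall).  For a
finite patch the mismatch reaching the front is attenuated by A =
tanh(a_theta/l) tanh(a_z/l) with the boundary-layer decay length
l = c sqrt(r_d h_f): thin-flap (shallow) tears transmit almost their full
mismatch at any size, thick-flap (deep) tears only when large, which is what
makes short deep tears the strongest configurations.  The mismatch is forced
through the front load path - cohesive spring in series with the
through-thickness matrix columns of the flap and the adventitia anchor - and
the false-lumen pressure wedges the torn faces apart; the intact-wall radial
stress at the tear plane (compressive) keeps clamping the un-opened
fraction:

    t_n = (1 - A) sigma_rr(R_d, P)
        + A [ delta / (1/K_nn + h_f/(6 C10_m) + t_a/(6 C10_a)) + w P ].

The circumferential shear traction is the shear-lag transfer of the flap's
released hoop prestretch.  Because 1/K_nn is orders of magnitude smaller
than the wall-column compliance, the result is insensitive to the cohesive
penalty stiffness.  The decay coefficient c and wedge factor w are the
model's two calibration constants (see the methods note).

theta-r tears (normal axial, the entry-tear geometry)
-----------------------------------------------------
The tear is a cross-sectional slit from the lumen to depth d.  The normal
traction on the front is the largest intact-wall axial Cauchy stress over
the torn depth band plus the pressure wedging the faces apart:
t_n = max sigma_zz(band) + P.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace
from math import sqrt, tanh

import numpy as np
import pandas as pd

from .cohesive import CohesiveParams, initiation_ratio
from .inflation import (
    VesselGeometry,
    _solve_inner_radius,
    _sigma_zz_minus_rr,
    _stress_diff,
    radial_stress_at,
    radius_map,
)
from .units import mmhg_to_kpa

__all__ = [
    "TearConfig",
    "CriticalPressureResult",
    "flap_partition",
    "tear_front_traction",
    "critical_pressure",
    "sweep",
]

THETA_Z = "theta_z"
THETA_R = "theta_r"

#: nominal loaded media thickness (mm) the catalogued tear depths refer to
NOMINAL_MEDIA_THICKNESS = 1.5

#: boundary-layer decay-length coefficient in l = c sqrt(r h).  Same order as
#: the classical axisymmetric-shell value (3(1-nu^2))^(-1/4) ~ 0.82 (nu = 1/2);
#: calibrated (with the wedge factor) to the study's critical-pressure envelope
DECAY_COEFF = 0.35

DEFAULT_P_MIN = 80.0
DEFAULT_P_MAX = 400.0
DEFAULT_N_LAYERS = 3
BISECTION_TOL_MMHG = 0.1


@dataclass(frozen=True)
class TearConfig:
    """A predefined tear: orientation, extent, depth and location label.

    ``depth`` is the radial distance (mm) of the tear plane from the lumen
    surface into the media, quoted on the study's nominal 1.5 mm media;
    ``extent_theta``/``extent_z`` are arc/axial lengths in mm (``extent_z`` is
    unused for theta-r tears, whose radial size is set by ``depth``).
    """

    orientation: str
    extent_theta: float
    extent_z: float = 0.0
    depth: float = 0.75
    location: str = ""
    aorta_id: str = ""

    def __post_init__(self) -> None:
        if self.orientation not in (THETA_Z, THETA_R):
            raise ValueError(
                f"orientation must be '{THETA_Z}' or '{THETA_R}', got {self.orientation!r}"
            )
        if self.extent_theta < 0 or self.extent_z < 0:
            raise ValueError("tear extents must be non-negative")
        if not 0.0 < self.depth < NOMINAL_MEDIA_THICKNESS:
            raise ValueError(
                f"depth must lie strictly inside the {NOMINAL_MEDIA_THICKNESS} mm media, "
                f"got {self.depth}"
            )


@dataclass(frozen=True)
class CriticalPressureResult:
    """Critical-pressure solve outcome for one (vessel, tear) case."""

    config: TearConfig
    critical_pressure: float  # mmHg
    limiting_component: str  # "normal" | "shear_s" | "shear_t"
    front_tractions: tuple[float, float, float]  # kPa, at the returned pressure
    converged: bool
    immediate_onset: bool = False


def _ngauss_for(n_layers: int) -> int:
    """Radial quadrature points per layer implied by the element count.

    Two Gauss points per through-thickness element; floor of 6 keeps the
    coarsest meshes well inside the smooth-integrand convergence regime.
    """
    return max(2 * n_layers, 6)


def _snap_depth(vessel: VesselGeometry, depth: float, n_layers: int) -> float:
    """Tear-plane depth in the vessel's own media, snapped to element centres.

    The catalogue depth is a fraction of the nominal 1.5 mm media; with
    ``n_layers`` through-thickness elements the tear plane sits at the centre
    of the nearest element, mirroring element-centre tear placement.
    """
    media = vessel.layers[0]
    frac = depth / NOMINAL_MEDIA_THICKNESS
    centres = (2.0 * np.arange(n_layers) + 1.0) / (2.0 * n_layers)
    frac_snapped = float(centres[np.argmin(np.abs(centres - frac))])
    return frac_snapped * media.thickness


def flap_partition(
    vessel: VesselGeometry,
    config: TearConfig,
    depth_override: float | None = None,
) -> tuple[VesselGeometry, VesselGeometry]:
    """Split the wall at the tear plane into (inner flap, outer shell).

    The flap is the media slice from the lumen to the tear plane (thickness =
    depth); the shell is the remaining media plus the adventitia.  Both
    inherit their GOH parameters, and the partition thicknesses sum exactly to
    the wall thickness.  ``depth_override`` supplies a depth already expressed
    in the vessel's own media (e.g. snapped to an element-centre grid).
    """
    media = vessel.layers[0]
    d = config.depth if depth_override is None else depth_override
    if not 0.0 < d < media.thickness:
        raise ValueError(
            f"tear depth {d} mm must lie strictly inside the media ({media.thickness} mm)"
        )
    flap_layer = _dc_replace(media, thickness=d)
    media_rest = _dc_replace(media, thickness=media.thickness - d)
    flap = VesselGeometry(vessel.inner_radius, (flap_layer,), vessel.axial_stretch)
    shell = VesselGeometry(
        vessel.inner_radius + d,
        (media_rest,) + vessel.layers[1:],
        vessel.axial_stretch,
    )
    return flap, shell


#: face-pressure wedging factor for theta-z fronts (calibration constant)
WEDGE_FACTOR_THETA_Z = 3.5


def _theta_z_traction(
    vessel: VesselGeometry,
    config: TearConfig,
    pressure: float,
    cohesive: CohesiveParams,
    n_layers: int,
) -> tuple[float, float, float]:
    d_local = _snap_depth(vessel, config.depth, n_layers)
    flap, _shell = flap_partition(vessel, config, depth_override=d_local)
    R_d = vessel.inner_radius + d_local
    ngauss = _ngauss_for(n_layers)

    # intact wall at P: loaded tear-plane radius and clamping radial stress
    ri_intact = _solve_inner_radius(vessel, pressure, ngauss)
    r_d = float(radius_map(vessel, ri_intact, R_d))
    sig_rr_d = radial_stress_at(vessel, ri_intact, R_d, ngauss)

    # prestretch-release mismatch: over the torn patch the flap (equal
    # pressure on both faces) springs back towards its stress-free radius
    delta_spring = r_d - R_d

    h_f = d_local
    ell = DECAY_COEFF * sqrt(r_d * h_f)
    a_theta = tanh(0.5 * config.extent_theta / ell)
    a_z = tanh(0.5 * config.extent_z / ell)
    attenuation = a_theta * a_z

    # series compliance of the front load path: cohesive spring + the
    # through-thickness matrix columns of the flap and the adventitia anchor
    k_nn, k_ss, _ = cohesive.stiffness
    adv = vessel.layers[-1]
    c_front = 1.0 / k_nn + h_f / (6.0 * flap.layers[0].c10) + adv.thickness / (6.0 * adv.c10)

    p_kpa = mmhg_to_kpa(pressure)
    t_n = (
        (1.0 - attenuation) * sig_rr_d
        + attenuation * (delta_spring / c_front + WEDGE_FACTOR_THETA_Z * p_kpa)
    )

    # shear-lag transfer of the flap's released hoop prestretch
    slip_strain = r_d / R_d - 1.0
    e_flap = 6.0 * flap.layers[0].c10
    c_shear = 1.0 / k_ss + sum(l.thickness / (2.0 * l.c10) for l in vessel.layers)
    t_s = a_theta * slip_strain * sqrt(e_flap * h_f / c_shear)
    return (t_n, t_s, 0.0)


def _theta_r_traction(
    vessel: VesselGeometry,
    config: TearConfig,
    pressure: float,
    n_layers: int,
    n_band: int = 33,
) -> tuple[float, float, float]:
    d_local = _snap_depth(vessel, config.depth, n_layers)
    R_d = vessel.inner_radius + d_local
    ri = _solve_inner_radius(vessel, pressure, _ngauss_for(n_layers))

    # sigma_zz over the torn band [R_i, R_d] (all inside the media)
    media = vessel.layers[0]
    lz = vessel.axial_stretch
    Rb = np.linspace(vessel.inner_radius, R_d, n_band)
    rb = np.asarray(radius_map(vessel, ri, Rb))
    lt = rb / Rb
    diff_tt = _stress_diff(lt, lz, media)
    diff_zz = _sigma_zz_minus_rr(lt, lz, media)
    integrand = diff_tt * Rb / (lz * rb * rb)
    sig_rr = -mmhg_to_kpa(pressure) + np.concatenate(
        ([0.0], np.cumsum(0.5 * (integrand[1:] + integrand[:-1]) * np.diff(Rb)))
    )
    sig_zz = sig_rr + diff_zz
    t_n = float(np.max(sig_zz)) + mmhg_to_kpa(pressure)
    return (t_n, 0.0, 0.0)


def tear_front_traction(
    vessel: VesselGeometry,
    config: TearConfig,
    pressure: float,
    cohesive: CohesiveParams,
    n_layers: int = DEFAULT_N_LAYERS,
) -> tuple[float, float, float]:
    """Cohesive traction (t_n, t_s, t_t) in kPa at the tear front.

    ``vessel`` is the zero-load geometry; ``pressure`` (mmHg) acts equally in
    the true and false lumen.  See the module docstring for the model.
    """
    if pressure < 0:
        raise ValueError("pressure must be non-negative")
    if config.orientation == THETA_Z:
        return _theta_z_traction(vessel, config, pressure, cohesive, n_layers)
    return _theta_r_traction(vessel, config, pressure, n_layers)


_COMPONENTS = ("normal", "shear_s", "shear_t")


def _limiting(traction: tuple[float, float, float], critical) -> str:
    ratios = (
        max(traction[0], 0.0) / critical[0],
        abs(traction[1]) / critical[1],
        abs(traction[2]) / critical[2],
    )
    return _COMPONENTS[int(np.argmax(ratios))]


def critical_pressure(
    vessel: VesselGeometry,
    config: TearConfig,
    cohesive: CohesiveParams,
    p_min: float = DEFAULT_P_MIN,
    p_max: float = DEFAULT_P_MAX,
    n_layers: int = DEFAULT_N_LAYERS,
    tol: float = BISECTION_TOL_MMHG,
) -> CriticalPressureResult:
    """Pressure (mmHg) at which the initiation ratio first reaches 1.

    Bisection on [p_min, p_max] to a bracket width of ``tol``.  If f >= 1
    already at the diastolic baseline ``p_min`` the case is flagged as
    immediate onset (critical pressure = p_min); if f < 1 at ``p_max`` a
    sentinel at ``p_max`` is returned with ``converged = False``.
    """

    def ratio(p: float) -> tuple[float, tuple[float, float, float]]:
        t = tear_front_traction(vessel, config, p, cohesive, n_layers)
        return initiation_ratio(t, cohesive.critical_tractions), t

    f_lo, t_lo = ratio(p_min)
    if f_lo >= 1.0:
        return CriticalPressureResult(
            config, p_min, _limiting(t_lo, cohesive.critical_tractions), t_lo,
            converged=True, immediate_onset=True,
        )
    f_hi, t_hi = ratio(p_max)
    if f_hi < 1.0:
        return CriticalPressureResult(
            config, p_max, _limiting(t_hi, cohesive.critical_tractions), t_hi,
            converged=False,
        )
    lo, hi = p_min, p_max
    t_at = t_hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        f_mid, t_mid = ratio(mid)
        if f_mid >= 1.0:
            hi, t_at = mid, t_mid
        else:
            lo = mid
    p_cr = 0.5 * (lo + hi)
    return CriticalPressureResult(
        config, p_cr, _limiting(t_at, cohesive.critical_tractions), t_at, converged=True
    )


def sweep(
    vessels,
    configs,
    cohesive: CohesiveParams,
    n_layers: int = DEFAULT_N_LAYERS,
    p_min: float = DEFAULT_P_MIN,
    p_max: float = DEFAULT_P_MAX,
) -> pd.DataFrame:
    """Cross-product critical-pressure evaluation, one row per (vessel, tear).

    ``vessels`` is a sequence of ``(label, diameter_mm, VesselGeometry)``
    triples (zero-load geometries) or bare geometries.  Individual failures
    are recorded per row (``error`` column) and the sweep continues; the
    ordering is deterministic and reruns are bitwise identical.
    """
    rows = []
    for vessel_entry in vessels:
        if isinstance(vessel_entry, VesselGeometry):
            label, diameter, vessel = "", float("nan"), vessel_entry
        else:
            label, diameter, vessel = vessel_entry
        for config in configs:
            row = {
                "aorta_id": config.aorta_id or label,
                "location": config.location,
                "diameter_mm": diameter,
                "orientation": config.orientation,
                "size_theta_mm": config.extent_theta,
                "size_z_mm": config.extent_z,
                "depth_mm": config.depth,
            }
            try:
                res = critical_pressure(
                    vessel, config, cohesive, p_min=p_min, p_max=p_max, n_layers=n_layers
                )
                row.update(
                    p_cr_mmHg=res.critical_pressure,
                    limiting_component=res.limiting_component,
                    converged=res.converged,
                    immediate_onset=res.immediate_onset,
                    error="",
                )
            except Exception as exc:  # pragma: no cover - per-row fault capture
                row.update(
                    p_cr_mmHg=float("nan"),
                    limiting_component="",
                    converged=False,
                    immediate_onset=False,
                    error=str(exc),
                )
            rows.append(row)
    return pd.DataFrame(rows)
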