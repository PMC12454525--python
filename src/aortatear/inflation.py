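"""Finite-strain inflation of a two-layer incompressible GOH cylinder.

The vessel is a straight thick-walled tube with restrained ends (plane strain,
lambda_z = 1 by default).  Incompressibility ties the deformed radius map to
the loaded inner radius alone,

    r(R)^2 = r_i^2 + (R^2 - R_i^2) / lambda_z ,

so equilibrium reduces to a single scalar equation: the lumen pressure is the
thick-wall integral P = int (sigma_tt - sigma_rr) / r dr across both layers.
``inflate`` root-finds the loaded inner radius for a prescribed pressure and
returns the transmural Cauchy stress profiles.

Pressures enter and leave in mmHg; stresses are kPa, lengths mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import cos, radians, sin, sqrt

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.optimize import brentq

from .material import GOHParameters
from .units import kpa_to_mmhg, mmhg_to_kpa

__all__ = [
    "VesselGeometry",
    "LoadedState",
    "radius_map",
    "equilibrium_pressure",
    "inflate",
    "laplace_hoop",
]

# default Gauss-Legendre points per layer for the pressure integral
_NGAUSS = 40


@dataclass(frozen=True)
class VesselGeometry:
    """Zero-load two-layer cylinder: inner radius + ordered layer stack.

    ``layers`` runs from the lumen outwards (media first, adventitia last in
    this study).  ``axial_stretch`` is the imposed lambda_z (1 = plane strain
    with restrained ends, the configuration used throughout).
    """

    inner_radius: float
    layers: tuple[GOHParameters, ...]
    axial_stretch: float = 1.0

    def __post_init__(self) -> None:
        if self.inner_radius <= 0:
            raise ValueError(f"inner_radius must be positive, got {self.inner_radius}")
        if not self.layers:
            raise ValueError("at least one layer is required")
        if self.axial_stretch <= 0:
            raise ValueError(f"axial_stretch must be positive, got {self.axial_stretch}")
        object.__setattr__(self, "layers", tuple(self.layers))

    @property
    def wall_thickness(self) -> float:
        return float(sum(layer.thickness for layer in self.layers))

    @property
    def outer_radius(self) -> float:
        return self.inner_radius + self.wall_thickness

    @property
    def interfaces(self) -> np.ndarray:
        """Radii of the layer boundaries, lumen to outer surface (len = n+1)."""
        return self.inner_radius + np.concatenate(
            ([0.0], np.cumsum([layer.thickness for layer in self.layers]))
        )


@dataclass(frozen=True)
class LoadedState:
    """Equilibrium configuration of a vessel at a given lumen pressure."""

    geometry: VesselGeometry
    pressure: float  # mmHg
    inner_radius_loaded: float  # mm
    radius_grid: np.ndarray  # reference radii R, mm
    radius_map: np.ndarray  # deformed radii r(R), mm
    sigma_rr: np.ndarray  # kPa
    sigma_tt: np.ndarray  # kPa
    sigma_zz: np.ndarray  # kPa


def radius_map(
    geom: VesselGeometry, inner_radius_loaded: float, R: np.ndarray | float
) -> np.ndarray | float:
    """Incompressible map R -> r given the loaded inner radius.

    Conserves the volume of every annulus exactly (with the axial stretch
    accounted for): r^2 = r_i^2 + (R^2 - R_i^2) / lambda_z.
    """
    if inner_radius_loaded <= 0:
        raise ValueError("inner_radius_loaded must be positive")
    R = np.asarray(R, dtype=float)
    r2 = inner_radius_loaded**2 + (R**2 - geom.inner_radius**2) / geom.axial_stretch
    return np.sqrt(r2)


def _stress_diff(lt: np.ndarray, lz: float, p: GOHParameters) -> np.ndarray:
    """sigma_tt - sigma_rr (deviatoric, q-independent) for incompressible states.

    Vectorised over the circumferential stretch array ``lt``.
    """
    lt = np.asarray(lt, dtype=float)
    lr = 1.0 / (lt * lz)
    a = radians(p.fiber_angle)
    c2, s2 = cos(a) ** 2, sin(a) ** 2
    i1 = lr * lr + lt * lt + lz * lz
    i4 = lt * lt * c2 + lz * lz * s2
    e = p.kappa * (i1 - 3.0) + (1.0 - 3.0 * p.kappa) * (i4 - 1.0)
    e_plus = np.maximum(e, 0.0)
    arg = p.k2 * e_plus * e_plus
    if np.any(arg > 700.0):
        raise OverflowError("fibre exponential overflow in stress evaluation")
    # dPsi/dEb summed over the two families, times dEb/dI4 etc.; the factor 2
    # from dI/dlambda = 2 lambda is folded in below
    w = 2.0 * p.k1 * e_plus * np.exp(arg)
    # lambda_i dPsi/dlambda_i differences
    s_tt = 2.0 * p.c10 * lt * lt + 2.0 * w * lt * lt * (p.kappa + (1.0 - 3.0 * p.kappa) * c2)
    s_rr = 2.0 * p.c10 * lr * lr + 2.0 * w * p.kappa * lr * lr
    return s_tt - s_rr


def _sigma_zz_minus_rr(lt: np.ndarray, lz: float, p: GOHParameters) -> np.ndarray:
    """sigma_zz - sigma_rr (q-independent) for incompressible states."""
    lt = np.asarray(lt, dtype=float)
    lr = 1.0 / (lt * lz)
    a = radians(p.fiber_angle)
    c2, s2 = cos(a) ** 2, sin(a) ** 2
    i1 = lr * lr + lt * lt + lz * lz
    i4 = lt * lt * c2 + lz * lz * s2
    e = p.kappa * (i1 - 3.0) + (1.0 - 3.0 * p.kappa) * (i4 - 1.0)
    e_plus = np.maximum(e, 0.0)
    w = 2.0 * p.k1 * e_plus * np.exp(p.k2 * e_plus * e_plus)
    s_zz = 2.0 * p.c10 * lz * lz + 2.0 * w * lz * lz * (p.kappa + (1.0 - 3.0 * p.kappa) * s2)
    s_rr = 2.0 * p.c10 * lr * lr + 2.0 * w * p.kappa * lr * lr
    return s_zz - s_rr


def _layer_gauss(geom: VesselGeometry, ngauss: int) -> list[tuple[GOHParameters, np.ndarray, np.ndarray]]:
    """Gauss nodes/weights in R for each layer."""
    out = []
    bounds = geom.interfaces
    xg, wg = leggauss(ngauss)
    for layer, Ra, Rb in zip(geom.layers, bounds[:-1], bounds[1:]):
        Rg = 0.5 * (Rb - Ra) * xg + 0.5 * (Ra + Rb)
        Wg = 0.5 * (Rb - Ra) * wg
        out.append((layer, Rg, Wg))
    return out


def equilibrium_pressure(
    geom: VesselGeometry, inner_radius_loaded: float, ngauss: int = _NGAUSS
) -> float:
    """Lumen pressure (mmHg) equilibrating the given loaded inner radius.

    P = int_{R_i}^{R_o} (sigma_tt - sigma_rr) R / (lambda_z r^2) dR, evaluated
    with ``ngauss`` Gauss-Legendre points per layer.
    """
    lz = geom.axial_stretch
    p_kpa = 0.0
    for layer, Rg, Wg in _layer_gauss(geom, ngauss):
        r = radius_map(geom, inner_radius_loaded, Rg)
        lt = r / Rg
        diff = _stress_diff(lt, lz, layer)
        p_kpa += float(np.sum(diff * Rg / (lz * r * r) * Wg))
    return kpa_to_mmhg(p_kpa)


def _solve_inner_radius(
    geom: VesselGeometry,
    pressure_mmhg: float,
    ngauss: int = _NGAUSS,
    max_inner_stretch: float = 1.6,
) -> float:
    if pressure_mmhg == 0.0:
        return geom.inner_radius
    lo = geom.inner_radius
    hi = geom.inner_radius * max_inner_stretch

    def f(ri: float) -> float:
        return equilibrium_pressure(geom, ri, ngauss) - pressure_mmhg

    f_hi = f(hi)
    if f_hi < 0.0:
        raise RuntimeError(
            f"inflation bracket failure: pressure {pressure_mmhg:.3f} mmHg exceeds "
            f"the supported range (P({max_inner_stretch:.2f} R_i) = "
            f"{f_hi + pressure_mmhg:.3f} mmHg); widen max_inner_stretch"
        )
    return brentq(f, lo, hi, xtol=1e-10, rtol=8.9e-16)


def inflate(
    geom: VesselGeometry,
    pressure: float,
    ngauss: int = _NGAUSS,
    n_profile: int = 41,
) -> LoadedState:
    """Solve the inflation equilibrium at ``pressure`` (mmHg).

    Returns the loaded state with transmural Cauchy stress profiles sampled on
    ``n_profile`` points per layer.  sigma_rr is integrated from the lumen
    (sigma_rr(inner) = -P) outwards; at equilibrium sigma_rr(outer) = 0 to the
    quadrature tolerance.
    """
    if pressure < 0:
        raise ValueError("pressure must be non-negative")
    ri = _solve_inner_radius(geom, pressure, ngauss)
    lz = geom.axial_stretch

    bounds = geom.interfaces
    grids = []
    for Ra, Rb in zip(bounds[:-1], bounds[1:]):
        grids.append(np.linspace(Ra, Rb, n_profile))
    Rgrid = np.concatenate(grids)
    rgrid = np.asarray(radius_map(geom, ri, Rgrid))

    # per-layer deviatoric stress differences on the profile grid
    diff_tt = np.empty_like(Rgrid)
    diff_zz = np.empty_like(Rgrid)
    for k, layer in enumerate(geom.layers):
        sl = slice(k * n_profile, (k + 1) * n_profile)
        lt = rgrid[sl] / Rgrid[sl]
        diff_tt[sl] = _stress_diff(lt, lz, layer)
        diff_zz[sl] = _sigma_zz_minus_rr(lt, lz, layer)

    # sigma_rr(r) = -P + int_{r_i}^{r} (sigma_tt - sigma_rr)/r' dr', per layer
    # to keep the integrand continuous within each segment
    p_kpa = mmhg_to_kpa(pressure)
    sigma_rr = np.empty_like(Rgrid)
    acc = -p_kpa
    for k in range(len(geom.layers)):
        sl = slice(k * n_profile, (k + 1) * n_profile)
        integrand = diff_tt[sl] * Rgrid[sl] / (lz * rgrid[sl] ** 2)
        seg = np.concatenate(
            ([0.0], np.cumsum(0.5 * (integrand[1:] + integrand[:-1]) * np.diff(Rgrid[sl])))
        )
        sigma_rr[sl] = acc + seg
        acc = sigma_rr[sl][-1]

    return LoadedState(
        geometry=geom,
        pressure=pressure,
        inner_radius_loaded=float(ri),
        radius_grid=Rgrid,
        radius_map=rgrid,
        sigma_rr=sigma_rr,
        sigma_tt=sigma_rr + diff_tt,
        sigma_zz=sigma_rr + diff_zz,
    )


def radial_stress_at(
    geom: VesselGeometry,
    inner_radius_loaded: float,
    R: float,
    ngauss: int = _NGAUSS,
) -> float:
    """sigma_rr (kPa) at reference radius R for the given loaded inner radius.

    Computed as -P + the partial thick-wall integral from the lumen to R.
    """
    lz = geom.axial_stretch
    p_kpa = mmhg_to_kpa(equilibrium_pressure(geom, inner_radius_loaded, ngauss))
    acc = -p_kpa
    bounds = geom.interfaces
    xg, wg = leggauss(ngauss)
    for layer, Ra, Rb in zip(geom.layers, bounds[:-1], bounds[1:]):
        Rb_eff = min(Rb, R)
        if Rb_eff <= Ra:
            break
        Rg = 0.5 * (Rb_eff - Ra) * xg + 0.5 * (Ra + Rb_eff)
        Wg = 0.5 * (Rb_eff - Ra) * wg
        r = np.asarray(radius_map(geom, inner_radius_loaded, Rg))
        diff = _stress_diff(r / Rg, lz, layer)
        acc += float(np.sum(diff * Rg / (lz * r * r) * Wg))
        if Rb_eff < Rb:
            break
    return acc


def stored_energy(geom: VesselGeometry, inner_radius_loaded: float, ngauss: int = _NGAUSS) -> float:
    """Stored strain energy per unit reference length, kPa*mm^2 (= mN)."""
    from .material import DeformationState, strain_energy

    lz = geom.axial_stretch
    total = 0.0
    for layer, Rg, Wg in _layer_gauss(geom, ngauss):
        r = np.asarray(radius_map(geom, inner_radius_loaded, Rg))
        lt = r / Rg
        psi = np.array(
            [strain_energy(DeformationState.incompressible(l, lz), layer) for l in lt]
        )
        total += float(np.sum(psi * 2.0 * np.pi * Rg * Wg))
    return total


def laplace_hoop(pressure: float, radius: float, thickness: float) -> float:
    """Law-of-Laplace hoop stress T = P R / h for a thin wall, kPa.

    ``pressure`` in mmHg, ``radius`` and ``thickness`` in mm.
    """
    if thickness <= 0:
        raise ValueError("thickness must be positive")
    return mmhg_to_kpa(pressure) * radius / thickness
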