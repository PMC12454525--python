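"""Gasser-Ogden-Holzapfel (GOH) fibre-dispersion hyperelasticity.

The arterial wall layers (media, adventitia) are modelled as incompressible
anisotropic hyperelastic solids with two symmetric collagen-fibre families at
+/- ``fiber_angle`` from the circumferential direction in the theta-z tangent
plane.  The strain energy per unit reference volume is

    Psi = C10 (I1b - 3) + k1/(2 k2) sum_a [exp(k2 <Eb_a>^2) - 1]

with the fibre strain-like quantity Eb_a = kappa (I1b - 3) + (1 - 3 kappa)
(I4b_a - 1) and the Macaulay bracket <x> = max(x, 0) switching the fibres off
in compression.  kappa in [0, 1/3] measures in-plane fibre dispersion
(0 = perfectly aligned, 1/3 = isotropic).  An optional volumetric penalty
(1/D)((J^2-1)/2 - ln J) is available, but the vessel solvers use exact
incompressibility (J = 1) with a Lagrange-multiplier reaction pressure.

All evaluations here are in principal stretches aligned with the cylindrical
axes (r, theta, z); the base states of the tube problems carry no shear.
Units: stresses and energy densities in kPa, lengths in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import cos, exp, log, radians, sin

import numpy as np

__all__ = [
    "GOHParameters",
    "DeformationState",
    "StressState",
    "macaulay",
    "fiber_strain",
    "isochoric_invariants",
    "strain_energy",
    "cauchy_stress",
]

# exp(k2 <E>^2) overflows double precision just above exp(709)
_EXP_ARG_LIMIT = 700.0


@dataclass(frozen=True)
class GOHParameters:
    """Per-layer constitutive constants and layer thickness.

    Parameters
    ----------
    c10 : float
        Ground-matrix (neo-Hookean) stiffness, kPa.
    k1 : float
        Fibre stiffness, kPa.
    k2 : float
        Dimensionless fibre stiffening exponent.
    kappa : float
        Fibre dispersion, in [0, 1/3].
    fiber_angle : float
        Mean fibre angle from the circumferential direction, degrees, in
        [0, 90]; the two families sit at +/- this angle in the theta-z plane.
    thickness : float
        Layer thickness, mm.
    name : str
        Optional layer label ("media", "adventitia", ...).
    """

    c10: float
    k1: float
    k2: float
    kappa: float
    fiber_angle: float
    thickness: float
    name: str = ""

    def __post_init__(self) -> None:
        if self.c10 <= 0:
            raise ValueError(f"c10 must be positive, got {self.c10}")
        if self.k1 < 0:
            raise ValueError(f"k1 must be non-negative, got {self.k1}")
        if self.k2 <= 0:
            raise ValueError(f"k2 must be positive, got {self.k2}")
        if not 0.0 <= self.kappa <= 1.0 / 3.0:
            raise ValueError(f"kappa must lie in [0, 1/3], got {self.kappa}")
        if not 0.0 <= self.fiber_angle <= 90.0:
            raise ValueError(
                f"fiber_angle must lie in [0, 90] degrees, got {self.fiber_angle}"
            )
        if self.thickness <= 0:
            raise ValueError(f"thickness must be positive, got {self.thickness}")


@dataclass(frozen=True)
class DeformationState:
    """Principal-stretch description of a local deformation.

    ``stretches`` is (lambda_r, lambda_theta, lambda_z) aligned with the
    cylindrical axes; ``jacobian`` is the volume ratio J.  The incompressible
    solvers always construct states with J = 1.
    """

    stretches: tuple[float, float, float]
    jacobian: float = 1.0

    def __post_init__(self) -> None:
        lr, lt, lz = self.stretches
        if min(lr, lt, lz) <= 0.0:
            raise ValueError(f"stretches must be positive, got {self.stretches}")
        if self.jacobian <= 0.0:
            raise ValueError(f"jacobian must be positive, got {self.jacobian}")

    @staticmethod
    def incompressible(lambda_theta: float, lambda_z: float = 1.0) -> "DeformationState":
        """State with lambda_r fixed by lambda_r * lambda_theta * lambda_z = 1."""
        return DeformationState((1.0 / (lambda_theta * lambda_z), lambda_theta, lambda_z))


@dataclass(frozen=True)
class StressState:
    """Cauchy stress in the axisymmetric base state (shears vanish), kPa."""

    cauchy: tuple[float, float, float]  # (sigma_rr, sigma_tt, sigma_zz)

    @property
    def sigma_rr(self) -> float:
        return self.cauchy[0]

    @property
    def sigma_tt(self) -> float:
        return self.cauchy[1]

    @property
    def sigma_zz(self) -> float:
        return self.cauchy[2]


def macaulay(x: float) -> float:
    """Macaulay bracket <x> = max(x, 0)."""
    return x if x > 0.0 else 0.0


def fiber_strain(i1bar: float, i4bar: float, kappa: float) -> float:
    """Fibre strain-like quantity Eb = kappa (I1b - 3) + (1 - 3 kappa)(I4b - 1)."""
    if not 0.0 <= kappa <= 1.0 / 3.0:
        raise ValueError(f"kappa must lie in [0, 1/3], got {kappa}")
    return kappa * (i1bar - 3.0) + (1.0 - 3.0 * kappa) * (i4bar - 1.0)


def _bar_stretches(state: DeformationState) -> tuple[float, float, float]:
    s = state.jacobian ** (-1.0 / 3.0)
    lr, lt, lz = state.stretches
    return lr * s, lt * s, lz * s


def isochoric_invariants(
    state: DeformationState, fiber_angle: float
) -> tuple[float, float, float]:
    """Isochoric invariants (I1b, I4b, I6b) for fibres at +/- fiber_angle.

    The fibre families lie in the theta-z tangent plane, so the +/- families
    share the same pseudo-invariant: I4b = I6b = lt^2 cos^2(a) + lz^2 sin^2(a).
    """
    lr, lt, lz = _bar_stretches(state)
    a = radians(fiber_angle)
    i1 = lr * lr + lt * lt + lz * lz
    i4 = lt * lt * cos(a) ** 2 + lz * lz * sin(a) ** 2
    return i1, i4, i4


def _fiber_terms(i1: float, i4: float, p: GOHParameters) -> tuple[float, float]:
    """Return (<Eb>, dPsi/dEb-like factor k1 <Eb> exp(k2 <Eb>^2)) for one family."""
    e = fiber_strain(i1, i4, p.kappa)
    e_plus = macaulay(e)
    arg = p.k2 * e_plus * e_plus
    if arg > _EXP_ARG_LIMIT:
        raise OverflowError(
            f"fibre exponential overflow: k2*<E>^2 = {arg:.3g} exceeds "
            f"{_EXP_ARG_LIMIT:g} (Eb = {e:.3g}); the stretch state is outside "
            "the physically meaningful range of the model"
        )
    return e_plus, arg


def strain_energy(
    state: DeformationState, p: GOHParameters, penalty_d: float | None = None
) -> float:
    """GOH strain-energy density, kPa.

    With ``penalty_d`` (the compressibility parameter D, kPa^-1) the dilatational
    penalty (1/D)((J^2-1)/2 - ln J) is added; by default the evaluation is on
    the exactly incompressible path and the term is omitted.
    """
    i1, i4, _ = isochoric_invariants(state, p.fiber_angle)
    psi = p.c10 * (i1 - 3.0)
    # two identical fibre families (+/- angle share I4)
    for _family in range(2):
        _, arg = _fiber_terms(i1, i4, p)
        psi += p.k1 / (2.0 * p.k2) * (exp(arg) - 1.0)
    if penalty_d is not None:
        j = state.jacobian
        psi += (1.0 / penalty_d) * ((j * j - 1.0) / 2.0 - log(j))
    return psi


def dpsi_dstretches(state: DeformationState, p: GOHParameters) -> np.ndarray:
    """Analytic (dPsi/dlr, dPsi/dlt, dPsi/dlz) on the incompressible path."""
    lr, lt, lz = state.stretches
    i1, i4, _ = isochoric_invariants(state, p.fiber_angle)
    a = radians(p.fiber_angle)
    c2, s2 = cos(a) ** 2, sin(a) ** 2

    grad = 2.0 * p.c10 * np.array([lr, lt, lz])
    e_plus, arg = _fiber_terms(i1, i4, p)
    if e_plus > 0.0:
        # dPsi/dEb per family = k1 * Eb * exp(k2 Eb^2); two families
        w = 2.0 * p.k1 * e_plus * exp(arg)
        di1 = 2.0 * np.array([lr, lt, lz])
        di4 = 2.0 * np.array([0.0, lt * c2, lz * s2])
        grad = grad + w * (p.kappa * di1 + (1.0 - 3.0 * p.kappa) * di4)
    return grad


def cauchy_stress(
    state: DeformationState, p: GOHParameters, reaction_pressure: float = 0.0
) -> StressState:
    """Cauchy stress for the incompressible material, kPa.

    sigma_ii = lambda_i dPsi/dlambda_i - q, with q the reaction pressure
    (Lagrange multiplier) fixed by equilibrium and boundary conditions at the
    vessel level; the deviatoric part is independent of q.
    """
    if abs(state.jacobian - 1.0) > 1e-10:
        raise ValueError(
            f"incompressible stress evaluation requires J = 1, got J = {state.jacobian}"
        )
    lam = np.asarray(state.stretches)
    sig = lam * dpsi_dstretches(state, p) - reaction_pressure
    return StressState(tuple(sig))
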