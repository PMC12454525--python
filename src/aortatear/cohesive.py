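"""Interface damage: traction-separation elasticity, onset criterion, softening.

The medial interface is a cohesive surface.  Before damage it responds
linearly, t = K delta, with a diagonal penalty stiffness K.  Tear initiation
follows the maximum-nominal-stress criterion

    f = max( <t_n>/t_n_cr, |t_s|/t_s_cr, |t_t|/t_t_cr ),  onset at f >= 1,

where the Macaulay bracket on the normal traction makes purely compressive
states harmless.  After onset a single scalar damage variable d grows with
the effective separation (norm of <delta_n>, delta_s, delta_t) along a linear
softening envelope sized so that the dissipated energy per unit area at full
decohesion equals the fracture energy G for any fixed mode mix; unloading and
reloading follow the damaged secant stiffness through the origin, and damage
is irreversible.  Normal stiffness in compression is retained undamaged
(contact-like) to prevent interpenetration.

Units: tractions kPa, separations mm, stiffness kPa/mm, energies kPa*mm
(numerically equal to N/m).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import sqrt

import numpy as np

__all__ = [
    "CohesiveParams",
    "TractionState",
    "elastic_traction",
    "initiation_ratio",
    "damage_update",
]

DEFAULT_PENALTY_STIFFNESS = 1.0e5  # kPa/mm; must dominate wall compliance


@dataclass(frozen=True)
class CohesiveParams:
    """Interface stiffness, critical tractions and fracture energy.

    ``stiffness`` = (K_nn, K_ss, K_tt) in kPa/mm; ``critical_tractions`` =
    (t_n_cr, t_s_cr, t_t_cr) in kPa; ``fracture_energy`` G in N/m (= kPa*mm).
    """

    stiffness: tuple[float, float, float] = (
        DEFAULT_PENALTY_STIFFNESS,
    ) * 3
    critical_tractions: tuple[float, float, float] = (131.0, 97.0, 120.0)
    fracture_energy: float = 50.0

    def __post_init__(self) -> None:
        if min(self.stiffness) <= 0:
            raise ValueError(f"stiffnesses must be positive, got {self.stiffness}")
        if min(self.critical_tractions) <= 0:
            raise ValueError(
                f"critical tractions must be positive, got {self.critical_tractions}"
            )
        if self.fracture_energy <= 0:
            raise ValueError(f"fracture_energy must be positive, got {self.fracture_energy}")
        # softening branch must exist: final separation beyond initiation
        for K, tcr in zip(self.stiffness, self.critical_tractions):
            d0 = tcr / K
            df = 2.0 * self.fracture_energy / tcr
            if df <= d0:
                raise ValueError(
                    f"no softening branch: 2G/t_cr = {df:.4g} mm <= t_cr/K = {d0:.4g} mm"
                )


@dataclass(frozen=True)
class TractionState:
    """Interface point state: traction, separation, damage, dissipation.

    ``delta0_eff``, ``t0_eff`` record the effective separation/traction at
    initiation (set once, when f first reaches 1); ``delta_max_eff`` tracks
    the largest effective separation seen, which drives the irreversible
    damage variable.
    """

    traction: tuple[float, float, float] = (0.0, 0.0, 0.0)
    separation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    damage: float = 0.0
    dissipated: float = 0.0
    delta0_eff: float | None = None
    t0_eff: float | None = None
    delta_max_eff: float = 0.0

    @property
    def initiated(self) -> bool:
        return self.delta0_eff is not None

    @property
    def failed(self) -> bool:
        return self.damage >= 1.0


def elastic_traction(
    separation: tuple[float, float, float], params: CohesiveParams
) -> tuple[float, float, float]:
    """Undamaged linear response t = diag(K) * delta."""
    return tuple(K * d for K, d in zip(params.stiffness, separation))


def initiation_ratio(
    traction: tuple[float, float, float],
    critical: tuple[float, float, float],
) -> float:
    """Maximum-nominal-stress ratio f; onset when f >= 1.

    The normal component passes through a Macaulay bracket (compression never
    initiates); the shear components enter by magnitude so shear of either
    sign can initiate.
    """
    if min(critical) <= 0:
        raise ValueError(f"critical tractions must be positive, got {critical}")
    tn, ts, tt = traction
    return max(max(tn, 0.0) / critical[0], abs(ts) / critical[1], abs(tt) / critical[2])


def _effective_separation(separation: tuple[float, float, float]) -> float:
    dn, ds, dt = separation
    return sqrt(max(dn, 0.0) ** 2 + ds * ds + dt * dt)


def _dissipated(d0: float, t0: float, df: float, dmax: float) -> float:
    """Energy per area dissipated up to peak effective separation ``dmax``.

    Area under the bilinear envelope up to dmax minus the recoverable secant
    energy; equals G = t0*df/2 at dmax = df.
    """
    if dmax <= d0:
        return 0.0
    dmax = min(dmax, df)
    t_env = t0 * (df - dmax) / (df - d0)
    area = 0.5 * t0 * d0 + 0.5 * (t0 + t_env) * (dmax - d0)
    return area - 0.5 * t_env * dmax


def damage_update(
    state: TractionState,
    new_separation: tuple[float, float, float],
    params: CohesiveParams,
) -> TractionState:
    """Advance the interface point to ``new_separation``.

    Elastic below onset; after the initiation ratio first reaches 1 the
    tensile/shear response softens linearly in the effective separation, with
    secant unloading through the origin and irreversible damage.  Compressive
    normal separation always responds with the full penalty stiffness.
    """
    if any(np.isnan(new_separation)):
        raise ValueError(f"NaN in separation {new_separation}")
    Kn, Ks, Kt = params.stiffness
    dn, ds, dt = new_separation
    de = _effective_separation(new_separation)

    d0, t0 = state.delta0_eff, state.t0_eff
    if d0 is None:
        trial = elastic_traction((max(dn, 0.0), ds, dt), params)
        f = initiation_ratio(trial, params.critical_tractions)
        if f < 1.0:
            tn = Kn * dn  # compression keeps full stiffness
            return replace(
                state,
                traction=(tn, Ks * ds, Kt * dt),
                separation=tuple(new_separation),
                delta_max_eff=max(state.delta_max_eff, de),
            )
        # onset inside this step: locate it by linear scaling of the step
        d0 = de / f
        t0_vec = tuple(t / f for t in trial)
        t0 = sqrt(sum(t * t for t in t0_vec))
        state = replace(state, delta0_eff=d0, t0_eff=t0)

    df = 2.0 * params.fracture_energy / t0
    dmax = max(state.delta_max_eff, de, d0)
    if dmax >= df:
        damage = 1.0
    else:
        damage = df * (dmax - d0) / (dmax * (df - d0))
        damage = min(max(damage, 0.0), 1.0)
    damage = max(damage, state.damage)  # irreversible

    g = 1.0 - damage
    tn = Kn * dn if dn < 0.0 else g * Kn * dn
    traction = (tn, g * Ks * ds, g * Kt * dt)
    dissipated = max(_dissipated(d0, t0, df, dmax), state.dissipated)
    return TractionState(
        traction=traction,
        separation=tuple(new_separation),
        damage=damage,
        dissipated=min(dissipated, params.fracture_energy),
        delta0_eff=d0,
        t0_eff=t0,
        delta_max_eff=dmax,
    )
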