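"""Two-layer tube inflation: kinematics, equilibrium, stress profiles."""

from math import pi, sqrt

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import minimize_scalar

from aortatear.inflation import (
    VesselGeometry,
    equilibrium_pressure,
    inflate,
    laplace_hoop,
    radius_map,
    stored_energy,
)
from aortatear.material import DeformationState, GOHParameters, fiber_strain, isochoric_invariants
from aortatear.units import mmhg_to_kpa


class TestRadiusMap:
    def test_identity_when_unloaded(self, vessel8):
        R = np.linspace(8.0, 10.0, 11)
        assert np.allclose(radius_map(vessel8, 8.0, R), R, rtol=0, atol=0)

    def test_algebraic_value(self, vessel8):
        # r(10)^2 = 9^2 + (10^2 - 8^2) = 117
        assert radius_map(vessel8, 9.0, 10.0) == pytest.approx(sqrt(117.0), rel=1e-15)

    def test_annulus_volume_conserved(self, vessel8):
        ri = 9.3
        for Ra, Rb in [(8.0, 8.7), (8.2, 9.9), (9.5, 10.0)]:
            vol_current, _ = quad(
                lambda R: 2 * pi * float(radius_map(vessel8, ri, R)) * R / float(radius_map(vessel8, ri, R)),
                Ra,
                Rb,
            )  # integrand r * dr/dR = R / lambda_z
            vol_reference = pi * (Rb**2 - Ra**2)
            assert vol_current == pytest.approx(vol_reference, rel=1e-12)


class TestEquilibriumPressure:
    def test_identity_configuration_is_unpressurised(self, vessel8):
        assert equilibrium_pressure(vessel8, 8.0) == pytest.approx(0.0, abs=1e-12)

    def test_strictly_monotone_in_inner_radius(self, vessel8):
        radii = 8.0 * np.linspace(1.0, 1.4, 21)
        pressures = [equilibrium_pressure(vessel8, r) for r in radii]
        assert all(b > a for a, b in zip(pressures, pressures[1:]))

    def test_thicker_wall_needs_more_pressure(self, layers):
        media, adventitia = layers
        thick = VesselGeometry(
            8.0,
            (
                GOHParameters(media.c10, media.k1, media.k2, media.kappa, media.fiber_angle, 3.0),
                GOHParameters(
                    adventitia.c10, adventitia.k1, adventitia.k2, adventitia.kappa,
                    adventitia.fiber_angle, 1.0,
                ),
            ),
        )
        thin = VesselGeometry(8.0, layers)
        assert equilibrium_pressure(thick, 9.0) > equilibrium_pressure(thin, 9.0)

    def test_grid_refinement_converged(self, vessel8):
        p40 = equilibrium_pressure(vessel8, 9.5, ngauss=40)
        p80 = equilibrium_pressure(vessel8, 9.5, ngauss=80)
        assert abs(p80 - p40) / abs(p80) < 1e-4

    def test_agrees_with_potential_energy_minimisation(self, layers):
        # single-layer neo-Hookean tube (k1 = 0); independent brute-force
        # oracle: minimise total potential over the radius map family
        media, _ = layers
        nh = GOHParameters(media.c10, 0.0, media.k2, media.kappa, media.fiber_angle, 2.0)
        geom = VesselGeometry(8.0, (nh,))
        for target in (8.4, 8.8, 9.6):
            p = equilibrium_pressure(geom, target)
            p_kpa = mmhg_to_kpa(p)

            def potential(ri):
                return stored_energy(geom, ri) - p_kpa * pi * (ri**2 - 8.0**2)

            res = minimize_scalar(potential, bounds=(8.01, 12.0), method="bounded",
                                  options={"xatol": 1e-10})
            assert res.x == pytest.approx(target, rel=1e-3)


class TestInflate:
    def test_zero_pressure_is_identity(self, vessel8):
        state = inflate(vessel8, 0.0)
        assert state.inner_radius_loaded == 8.0
        assert np.allclose(state.radius_map, state.radius_grid)
        assert np.allclose(state.sigma_tt - state.sigma_rr, 0.0, atol=1e-12)

    def test_radial_stress_boundary_conditions(self, vessel8):
        state = inflate(vessel8, 80.0)
        p_kpa = mmhg_to_kpa(80.0)
        assert state.sigma_rr[0] == pytest.approx(-p_kpa, rel=1e-12)
        assert abs(state.sigma_rr[-1]) < 1e-3 * p_kpa

    def test_radial_stress_continuous_at_interface(self, vessel8):
        state = inflate(vessel8, 80.0, n_profile=41)
        assert state.sigma_rr[40] == pytest.approx(state.sigma_rr[41], abs=1e-9)

    def test_radius_map_monotone_and_volume_exact(self, vessel8):
        state = inflate(vessel8, 120.0)
        # the profile grid repeats the interface point; r must strictly
        # increase wherever R does
        increasing_R = np.diff(state.radius_grid) > 0
        assert np.all(np.diff(state.radius_map)[increasing_R] > 0)
        lhs = state.radius_map**2
        rhs = state.inner_radius_loaded**2 + (state.radius_grid**2 - 64.0)
        assert np.allclose(lhs, rhs, rtol=1e-10)

    def test_fibres_in_tension_at_diastole(self, vessel8):
        # 80 mmHg keeps every collagen family engaged through the wall
        state = inflate(vessel8, 80.0)
        n = len(state.radius_grid) // len(vessel8.layers)
        for k, layer in enumerate(vessel8.layers):
            sl = slice(k * n, (k + 1) * n)
            for R, r in zip(state.radius_grid[sl], state.radius_map[sl]):
                d = DeformationState.incompressible(r / R, 1.0)
                i1, i4, _ = isochoric_invariants(d, layer.fiber_angle)
                assert fiber_strain(i1, i4, layer.kappa) > 0.0

    def test_bracket_failure_is_informative(self, vessel8):
        with pytest.raises(RuntimeError, match="bracket"):
            inflate(vessel8, 1e5)

    def test_external_work_equals_stored_energy(self, vessel8):
        # quasi-static inflation path: trapezoidal int P d(pi r_i^2)
        pressures = np.linspace(0.0, 80.0, 161)
        radii = [inflate(vessel8, p).inner_radius_loaded for p in pressures]
        areas = pi * np.asarray(radii) ** 2
        p_kpa = mmhg_to_kpa(pressures)
        work = float(np.sum(0.5 * (p_kpa[1:] + p_kpa[:-1]) * np.diff(areas)))
        stored = stored_energy(vessel8, radii[-1])
        assert work == pytest.approx(stored, rel=5e-3)


def test_stress_diff_consistent_with_material_module(layers):
    # the vectorised tube integrand must agree with the pointwise
    # constitutive evaluation sigma_tt - sigma_rr
    from aortatear.inflation import _sigma_zz_minus_rr, _stress_diff
    from aortatear.material import cauchy_stress

    for p in layers:
        for lt in (1.02, 1.1, 1.25):
            state = DeformationState.incompressible(lt, 1.0)
            sig = cauchy_stress(state, p)
            assert float(_stress_diff(np.array([lt]), 1.0, p)[0]) == pytest.approx(
                sig.sigma_tt - sig.sigma_rr, rel=1e-12
            )
            assert float(_sigma_zz_minus_rr(np.array([lt]), 1.0, p)[0]) == pytest.approx(
                sig.sigma_zz - sig.sigma_rr, rel=1e-12
            )


class TestLaplace:
    def test_arithmetic_with_unit_conversion(self):
        assert laplace_hoop(80.0, 10.0, 2.0) == pytest.approx(53.33, abs=0.01)

    def test_doubling_thickness_halves_stress(self):
        assert laplace_hoop(80.0, 10.0, 4.0) == laplace_hoop(80.0, 10.0, 2.0) / 2.0

    def test_thin_wall_limit_matches_full_solution(self, layers):
        # h/R = 0.01 single-layer tube: mean hoop stress within 2% of Laplace
        media, _ = layers
        thin = GOHParameters(media.c10, media.k1, media.k2, media.kappa, media.fiber_angle, 1.0)
        geom = VesselGeometry(100.0, (thin,))
        state = inflate(geom, 20.0)
        mean_hoop = float(np.mean(state.sigma_tt))
        r_mid = 0.5 * (state.radius_map[0] + state.radius_map[-1])
        h = state.radius_map[-1] - state.radius_map[0]
        laplace = mmhg_to_kpa(20.0) * r_mid / h
        assert mean_hoop == pytest.approx(laplace, rel=0.02)
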