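"""Drop-shape solver: physical limits, invariants and inversion."""

import numpy as np
import pytest

from vitellometrics import (
    BondNumberError,
    BracketError,
    DegenerateProfileError,
    DropProfile,
    MembraneDropParams,
    invert_tension,
    minimum_energy_profile,
    solve_drop_shape,
    tension_ratio,
    yolk_index,
)

from conftest import GRAVITY, YOLK_DENSITY, YOLK_VOLUME, params_at_bond


class TestForwardSolver:
    def test_sphere_limit(self):
        """At negligible gravity the membrane pulls the yolk into a sphere."""
        profile = solve_drop_shape(params_at_bond(0.01))
        assert profile.yolk_index == pytest.approx(1.0, rel=0.02)

    def test_pancake_limit_height(self):
        """Strong flattening approaches the puddle height 2*sqrt(gamma/rho g)."""
        p = params_at_bond(1000.0)
        profile = solve_drop_shape(p)
        assert profile.height == pytest.approx(2.0 * p.capillary_length, rel=0.05)

    def test_pancake_height_value(self):
        """gamma = 0.5 N/m over yolk-density fluid flattens to ~14.04 mm."""
        gamma, rho = 0.5, YOLK_DENSITY
        volume = (1000.0 * gamma / (rho * GRAVITY)) ** 1.5  # Bo = 1000
        profile = solve_drop_shape(MembraneDropParams(gamma, rho, volume))
        assert profile.height * 1e3 == pytest.approx(14.04, rel=0.05)

    def test_asymptotic_branch_continuity(self):
        """Collocation and pancake-asymptotic branches agree near the switch."""
        lo = solve_drop_shape(params_at_bond(1.4e3))
        hi = solve_drop_shape(params_at_bond(1.6e3))
        # height scales ~ Bo^(-1/2); compare after removing that trend
        ratio = (lo.height / hi.height) / (1.6e3 / 1.4e3) ** 0.5
        assert ratio == pytest.approx(1.0, abs=0.01)

    def test_volume_conservation(self):
        for bo in [0.01, 0.5, 5.0, 50.0, 500.0, 5e3]:
            p = params_at_bond(bo)
            profile = solve_drop_shape(p, rtol=1e-6)
            assert abs(profile.enclosed_volume - p.volume) / p.volume <= 1e-6

    def test_yolk_index_monotone_in_tension(self, yolk_params):
        gammas = np.geomspace(0.05, 5.0, 10)
        yis = [
            solve_drop_shape(
                MembraneDropParams(g, yolk_params["density"], yolk_params["volume"])
            ).yolk_index
            for g in gammas
        ]
        assert np.all(np.diff(yis) > 0)

    def test_dimensional_invariance(self, yolk_params):
        """Rescaling lengths by k and tension by k^2 rescales the shape by k."""
        k = 3.0
        base = MembraneDropParams(0.4, yolk_params["density"], yolk_params["volume"])
        scaled = MembraneDropParams(
            0.4 * k**2, yolk_params["density"], yolk_params["volume"] * k**3
        )
        a = solve_drop_shape(base)
        b = solve_drop_shape(scaled)
        assert b.height == pytest.approx(k * a.height, rel=1e-9)
        assert b.diameter == pytest.approx(k * a.diameter, rel=1e-9)
        assert b.yolk_index == pytest.approx(a.yolk_index, rel=1e-9)

    def test_meridian_structure(self):
        profile = solve_drop_shape(params_at_bond(5.0))
        r, z = profile.meridian.T
        assert r[0] == 0.0 and z[0] == pytest.approx(profile.height)
        assert z[-1] == 0.0
        assert np.all(np.diff(z) < 0)
        assert profile.diameter >= 2.0 * profile.base_radius
        # diameter is the refined equator width, at least the sampled maximum
        assert profile.diameter >= 2.0 * r.max() - 1e-12
        assert profile.diameter == pytest.approx(2.0 * r.max(), rel=1e-5)

    def test_bond_number_domain(self):
        with pytest.raises(BondNumberError):
            solve_drop_shape(params_at_bond(1e5))
        with pytest.raises(BondNumberError):
            solve_drop_shape(params_at_bond(1e-4))

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            MembraneDropParams(-0.1, 1000.0, 1e-6)
        with pytest.raises(ValueError):
            MembraneDropParams(0.1, 1000.0, 0.0)
        with pytest.raises(ValueError):
            solve_drop_shape(params_at_bond(1.0), rtol=0.5)


class TestYolkIndex:
    def test_direct_ratio(self):
        profile = DropProfile(
            meridian=np.array([[0.0, 0.01], [0.02, 0.0]]),
            height=0.010,
            diameter=0.040,
            base_radius=0.02,
            enclosed_volume=1e-5,
            params=MembraneDropParams(0.5, 1035.0, 1e-5),
        )
        assert yolk_index(profile) == pytest.approx(0.25)

    def test_sphere_is_unity(self):
        profile = solve_drop_shape(params_at_bond(0.001 * 10))  # Bo = 0.01
        assert profile.height / profile.diameter == pytest.approx(1.0, rel=0.02)

    def test_zero_diameter_degenerate(self):
        profile = DropProfile(
            meridian=np.zeros((2, 2)),
            height=0.01,
            diameter=0.0,
            base_radius=0.0,
            enclosed_volume=1e-5,
            params=MembraneDropParams(0.5, 1035.0, 1e-5),
        )
        with pytest.raises(DegenerateProfileError):
            yolk_index(profile)


class TestEnergyOracle:
    """Cross-method agreement between collocation and energy minimization."""

    def test_sphere_minimizes_area(self):
        profile = minimum_energy_profile(params_at_bond(0.01))
        radius = (3.0 * YOLK_VOLUME / (4.0 * np.pi)) ** (1.0 / 3.0)
        assert profile.height == pytest.approx(2.0 * radius, rel=0.02)
        assert profile.diameter == pytest.approx(2.0 * radius, rel=0.02)

    @pytest.mark.parametrize("bo", [0.5, 5.0, 50.0])
    def test_agreement_with_collocation(self, bo):
        p = params_at_bond(bo)
        ode = solve_drop_shape(p)
        oracle = minimum_energy_profile(p)
        assert oracle.height == pytest.approx(ode.height, rel=0.02)
        assert oracle.diameter == pytest.approx(ode.diameter, rel=0.02)

    def test_pancake_limit(self):
        p = params_at_bond(50.0)
        oracle = minimum_energy_profile(p)
        assert oracle.height == pytest.approx(2.0 * p.capillary_length, rel=0.05)

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            minimum_energy_profile(params_at_bond(1.0), n_grid=10)


class TestInversion:
    def test_round_trip(self, yolk_params):
        truth = 0.3
        profile = solve_drop_shape(
            MembraneDropParams(truth, yolk_params["density"], yolk_params["volume"])
        )
        est = invert_tension(
            profile.yolk_index, yolk_params["volume"], yolk_params["density"]
        )
        assert est == pytest.approx(truth, rel=1e-3)

    def test_accepts_height_diameter_pair(self, yolk_params):
        profile = solve_drop_shape(
            MembraneDropParams(0.3, yolk_params["density"], yolk_params["volume"])
        )
        est = invert_tension(
            (profile.height, profile.diameter),
            yolk_params["volume"],
            yolk_params["density"],
        )
        assert est == pytest.approx(0.3, rel=1e-3)

    def test_near_sphere_needs_unbounded_tension(self, yolk_params):
        with pytest.raises(BracketError):
            invert_tension(
                0.999, yolk_params["volume"], yolk_params["density"]
            )

    def test_flattened_yolk_in_reported_band(self, yolk_params):
        """A day-2-like flattened puddle inverts to 0.1-1 N/m."""
        gamma = invert_tension(
            0.25, yolk_params["volume"], yolk_params["density"]
        )
        assert 0.1 <= gamma <= 1.0

    def test_observed_index_validation(self, yolk_params):
        with pytest.raises(ValueError):
            invert_tension(1.5, yolk_params["volume"], yolk_params["density"])


class TestTensionRatio:
    def test_identity(self, yolk_params):
        ratio = tension_ratio(
            0.35, 0.35, yolk_params["volume"], yolk_params["density"]
        )
        assert ratio == pytest.approx(1.0, rel=1e-6)

    def test_pancake_square_law(self, yolk_params):
        """Deep in the pancake regime tension scales as height squared."""
        gamma_a = 0.05  # Bo ~ 134
        gamma_b = 0.63**2 * gamma_a
        rho, vol = yolk_params["density"], yolk_params["volume"]
        h_a = solve_drop_shape(MembraneDropParams(gamma_a, rho, vol)).height
        h_b = solve_drop_shape(MembraneDropParams(gamma_b, rho, vol)).height
        assert h_b / h_a == pytest.approx(0.63, rel=0.02)

    def test_day2_fraction_of_day0(self, yolk_params):
        """Flat (yi 0.25) vs round (yi 0.45) puddles: ~40% tension retained."""
        ratio = tension_ratio(
            0.45, 0.25, yolk_params["volume"], yolk_params["density"]
        )
        assert 0.30 <= ratio <= 0.55
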