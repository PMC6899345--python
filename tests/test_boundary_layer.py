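"""Dimensionless numbers, convection regimes and conductances."""

import math

import numpy as np
import pytest

import leafenergy as le
from leafenergy.boundary_layer import AR_FORCED_MAX, AR_FREE_MIN


class TestReynolds:
    def test_still_air(self):
        assert le.reynolds_number(0.0, 0.1, 1.55e-5) == 0.0

    def test_default_conditions(self):
        assert le.reynolds_number(2.0, 0.1, 1.55e-5) == pytest.approx(1.29e4, rel=0.01)

    def test_linear_in_wind_and_size(self):
        re = le.reynolds_number(2.0, 0.1, 1.55e-5)
        assert le.reynolds_number(4.0, 0.1, 1.55e-5) == pytest.approx(2 * re, rel=1e-12)
        assert le.reynolds_number(2.0, 0.2, 1.55e-5) == pytest.approx(2 * re, rel=1e-12)


class TestGrashof:
    def test_no_buoyancy_without_temperature_difference(self):
        assert le.grashof_number(0.1, 300.0, 300.0, 1.55e-5) == 0.0

    def test_flat_plate_magnitude(self):
        # 9.8 × 0.1³ × 5 / (300 × (1.55e-5)²)
        gr = le.grashof_number(0.1, 305.0, 300.0, 1.55e-5)
        assert gr == pytest.approx(6.80e5, rel=0.01)

    def test_cubic_in_leaf_size(self):
        gr = le.grashof_number(0.1, 305.0, 300.0, 1.55e-5)
        assert le.grashof_number(0.2, 305.0, 300.0, 1.55e-5) == pytest.approx(
            8 * gr, rel=1e-12
        )

    def test_symmetric_in_sign_of_difference(self):
        warm = le.grashof_number(0.1, 305.0, 300.0, 1.55e-5)
        # buoyancy magnitude depends on |ΔT_v|, not its sign
        assert le.grashof_number(0.1, 295.0, 300.0, 1.55e-5) == pytest.approx(
            warm, rel=1e-12
        )


class TestArchimedesClassification:
    def test_definitional_values(self):
        assert le.archimedes_number(0.0, 100.0) == 0.0
        assert le.archimedes_number(100.0 ** 2, 100.0) == 1.0

    def test_still_air_is_free_without_computing_ar(self):
        with pytest.raises(ValueError):
            le.archimedes_number(1e5, 0.0)
        assert le.classify_convection(1e5, 0.0) == "free"

    @pytest.mark.parametrize(
        "ar, regime",
        [
            (0.0, "forced"),
            (0.099, "forced"),
            (0.1, "mixed"),
            (1.0, "mixed"),
            (10.0, "mixed"),
            (10.001, "free"),
            (1e4, "free"),
        ],
    )
    def test_regime_thresholds(self, ar, regime):
        re = 100.0
        assert le.classify_convection(ar * re ** 2, re) == regime

    def test_ar_increases_with_leaf_size_at_fixed_wind(self):
        # Gr ∝ d³ while Re² ∝ d², so Ar ∝ d
        ars = []
        for d in (0.004, 0.04, 0.4):
            re = le.reynolds_number(2.0, d, 1.55e-5)
            gr = le.grashof_number(d, 303.0, 300.0, 1.55e-5)
            ars.append(le.archimedes_number(gr, re))
        assert ars[0] < ars[1] < ars[2]


class TestNusseltSherwood:
    def test_pure_forced_collapse_is_exact(self):
        cons = le.default_constants()
        re = 2000.0
        a, b = cons.nu_coefs["forced_laminar"]
        assert le.nusselt_number(re, 0.0, cons) == a * re ** b

    def test_pure_free_collapse_is_exact(self):
        cons = le.default_constants()
        gr = 1e6
        c, d = cons.nu_coefs["free"]
        assert le.nusselt_number(0.0, gr, cons, "upper", True) == c * gr ** d

    def test_laminar_turbulent_jump_at_critical_reynolds(self):
        cons = le.default_constants()
        below = le.nusselt_number(cons.Re_crit, 0.0, cons)
        above = le.nusselt_number(cons.Re_crit * (1 + 1e-12), 0.0, cons)
        al, bl = cons.nu_coefs["forced_laminar"]
        at, bt = cons.nu_coefs["forced_turbulent"]
        assert below == pytest.approx(al * cons.Re_crit ** bl, rel=1e-12)
        assert above == pytest.approx(at * cons.Re_crit ** bt, rel=1e-9)
        assert abs(below - above) > 1.0  # a genuine discontinuity

    def test_free_convection_damped_on_stratified_side(self):
        cons = le.default_constants()
        gr = 1e6
        upper_warm = le.nusselt_number(0.0, gr, cons, "upper", True)
        lower_warm = le.nusselt_number(0.0, gr, cons, "lower", True)
        assert lower_warm == pytest.approx(cons.free_asymmetry * upper_warm, rel=1e-12)
        # mirrored when the leaf is cooler than the air
        assert le.nusselt_number(0.0, gr, cons, "lower", False) == upper_warm
        assert le.nusselt_number(0.0, gr, cons, "upper", False) == lower_warm

    def test_mixed_between_components_and_bound(self):
        cons = le.default_constants()
        re, gr = 5000.0, 1e7
        nu = le.nusselt_number(re, gr, cons)
        forced = le.nusselt_number(re, 0.0, cons)
        free = le.nusselt_number(0.0, gr, cons)
        m = cons.mixing_exponent
        assert nu >= forced and nu >= free
        assert nu <= 2 ** (1 / m) * max(forced, free) * (1 + 1e-12)

    def test_sherwood_shares_coefficients_and_is_continuous_in_gr(self):
        cons = le.default_constants()
        assert le.sherwood_number(3000.0, 5e5, cons) == le.nusselt_number(
            3000.0, 5e5, cons
        )
        grs = np.linspace(0.0, 1e6, 50)
        shs = [le.sherwood_number(3000.0, g, cons) for g in grs]
        assert all(
            abs(a - b) < 0.1 * (shs[-1] - shs[0] + 1) for a, b in zip(shs, shs[1:])
        )


class TestConductances:
    def test_molar_to_velocity(self):
        assert le.molar_to_velocity(0.0, 298.15) == 0.0
        assert le.molar_to_velocity(5.0, 298.15) == pytest.approx(0.0124, abs=2e-4)
        v = le.molar_to_velocity(5.0, 298.15)
        assert le.molar_to_velocity(10.0, 298.15) == pytest.approx(2 * v, rel=1e-12)

    def test_boundary_conductance_scalings(self):
        g = le.boundary_conductance(50.0, 2.15e-5, 0.1)
        assert g == pytest.approx(1.075e-2, rel=1e-9)
        assert le.boundary_conductance(100.0, 2.15e-5, 0.1) == pytest.approx(
            2 * g, rel=1e-12
        )
        assert le.boundary_conductance(50.0, 2.15e-5, 0.2) == pytest.approx(
            g / 2, rel=1e-12
        )

    def test_sealed_leaf_has_zero_conductance(self):
        assert le.total_water_conductance(0.0, 0.0, 0.5, 0.01, 0.01, 298.15) == 0.0

    def test_infinite_boundary_layer_limit(self):
        g_tw = le.total_water_conductance(5.0, 0.1, 0.5, 1e12, 1e12, 298.15)
        assert g_tw == pytest.approx(le.molar_to_velocity(5.1, 298.15), rel=1e-6)

    def test_series_resistance_only_reduces_conductance(self, rng):
        for _ in range(50):
            g_sw = float(rng.uniform(0, 10))
            g_uw = float(rng.uniform(0, 1))
            sr = float(rng.uniform(0, 1))
            gb_u = float(rng.uniform(1e-4, 0.1))
            gb_l = float(rng.uniform(1e-4, 0.1))
            g_tw = le.total_water_conductance(g_sw, g_uw, sr, gb_u, gb_l, 298.15)
            assert 0.0 <= g_tw <= le.molar_to_velocity(g_sw + g_uw, 298.15) + 1e-18

    def test_amphistomatous_maximizes_conductance(self):
        """With equal boundary layers, g_tw peaks at SR = 0.5, symmetrically."""
        srs = np.linspace(0.0, 1.0, 101)
        gs = [le.total_water_conductance(5.0, 0.1, s, 0.01, 0.01, 298.15) for s in srs]
        assert int(np.argmax(gs)) == 50
        np.testing.assert_allclose(gs, gs[::-1], rtol=1e-12)


def test_nonnegative_outputs_for_valid_inputs(rng):
    cons = le.default_constants()
    for _ in range(30):
        re = float(rng.uniform(0, 1e5))
        gr = float(rng.uniform(0, 1e8))
        for surface in ("upper", "lower"):
            for warm in (True, False):
                assert le.nusselt_number(re, gr, cons, surface, warm) >= 0.0
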