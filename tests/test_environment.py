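"""Derived environmental physics against independent reference values."""

import math

import pytest

import leafenergy as le
from leafenergy.units import Quantity

# CRC / steam-table saturation vapour pressures over liquid water, kPa
PSAT_REFERENCE = {
    273.15: 0.6113,
    283.15: 1.2281,
    298.15: 3.1699,
    313.15: 7.3849,
    318.15: 9.5898,
}

# molar latent heat of vaporization, J mol⁻¹ (2500.9 and 2441.7 J g⁻¹ × 18.015 g mol⁻¹)
HVAP_REFERENCE = {273.15: 4.506e4, 298.15: 4.399e4}


class TestSaturationVaporPressure:
    @pytest.mark.parametrize("T, ref", sorted(PSAT_REFERENCE.items()))
    def test_within_one_percent_of_reference(self, T, ref):
        assert le.saturation_vapor_pressure(T) == pytest.approx(ref, rel=0.01)

    def test_strictly_increasing(self):
        ts = [245.0 + 5.0 * i for i in range(19)]
        ps = [le.saturation_vapor_pressure(t) for t in ts]
        assert all(a < b for a, b in zip(ps, ps[1:]))

    @pytest.mark.parametrize("T", [239.0, 341.0, 100.0])
    def test_out_of_range_rejected(self, T):
        with pytest.raises(ValueError, match="range"):
            le.saturation_vapor_pressure(T)

    def test_units_path_matches(self):
        assert le.saturation_vapor_pressure(Quantity(298.15, "K")).m_as(
            "kPa"
        ) == le.saturation_vapor_pressure(298.15)


class TestAirVaporPressure:
    def test_limits_and_midpoint(self):
        p_sat = le.saturation_vapor_pressure(298.15)
        assert le.air_vapor_pressure(p_sat, 0.0) == 0.0
        assert le.air_vapor_pressure(p_sat, 1.0) == p_sat
        assert le.air_vapor_pressure(p_sat, 0.5) == pytest.approx(1.58, abs=0.01)

    def test_rh_out_of_range(self):
        with pytest.raises(ValueError, match="RH"):
            le.air_vapor_pressure(3.17, 1.5)


class TestLatentHeat:
    @pytest.mark.parametrize("T, ref", sorted(HVAP_REFERENCE.items()))
    def test_reference_values(self, T, ref):
        assert le.latent_heat_vaporization(T) == pytest.approx(ref, rel=0.01)

    def test_strictly_decreasing(self):
        assert le.latent_heat_vaporization(310.0) < le.latent_heat_vaporization(290.0)


class TestDryAirDensity:
    def test_default_conditions(self):
        # 101324.6 Pa / (287.058 J kg⁻¹ K⁻¹ × 298.15 K) = 1.1838 kg m⁻³
        rho = le.dry_air_density(101.3246, 298.15)
        assert rho == pytest.approx(101324.6 / (287.058 * 298.15) * 1e3, rel=1e-12)
        assert rho == pytest.approx(1.184e3, rel=1e-3)

    def test_ideal_gas_proportionality(self):
        rho = le.dry_air_density(100.0, 300.0)
        assert le.dry_air_density(100.0, 600.0) == pytest.approx(rho / 2, rel=1e-12)
        assert le.dry_air_density(200.0, 300.0) == pytest.approx(rho * 2, rel=1e-12)


class TestSkyTemperature:
    def test_zero_insolation_limit(self):
        assert le.sky_temperature(298.15, 0.0) == 298.15

    @pytest.mark.parametrize("S_sw, expected", [(1000.0, 278.15), (500.0, 288.15)])
    def test_linear_offset(self, S_sw, expected):
        assert le.sky_temperature(298.15, S_sw) == pytest.approx(expected, abs=1e-12)

    def test_replaceable_in_solver(self):
        # an isothermal-sky model is a one-line substitution
        sol = le.solve_equilibrium(sky_model=lambda T_air, S_sw: T_air)
        assert sol.convergence == 0
        assert sol.derived.T_sky == 298.15


class TestIncidentLongwave:
    def test_isothermal_sky(self):
        # 2 σ T⁴ at 298.15 K
        assert le.incident_longwave(298.15, 298.15) == pytest.approx(896.1, abs=0.5)

    def test_clear_sky(self):
        assert le.incident_longwave(278.15, 298.15) == pytest.approx(787.4, abs=0.5)

    def test_stefan_boltzmann_homogeneity(self):
        base = le.incident_longwave(280.0, 300.0)
        assert le.incident_longwave(280.0 * 1.1, 300.0 * 1.1) == pytest.approx(
            base * 1.1 ** 4, rel=1e-12
        )


class TestScaleDiffusivity:
    def test_reference_state_exact(self):
        assert le.scale_diffusivity(21.2e-6, 273.15, 101.3246) == 21.2e-6

    def test_water_vapor_at_25C(self):
        d = le.scale_diffusivity(21.2e-6, 298.15, 101.3246)
        assert d == pytest.approx(21.2e-6 * (298.15 / 273.15) ** 1.75, rel=1e-12)
        assert d == pytest.approx(2.47e-5, rel=0.01)

    def test_inverse_pressure_scaling(self):
        d1 = le.scale_diffusivity(19.0e-6, 298.15, 101.3246)
        assert le.scale_diffusivity(19.0e-6, 298.15, 101.3246 / 2) == pytest.approx(
            2 * d1, rel=1e-12
        )


class TestVirtualTemperature:
    def test_dry_air_limit(self):
        assert le.virtual_temperature(298.15, 0.0, 101.3246) == 298.15

    def test_moist_air_example(self):
        assert le.virtual_temperature(298.15, 1.584, 101.3246) == pytest.approx(
            299.9, abs=0.05
        )

    def test_strictly_increasing_in_vapor_pressure(self):
        tvs = [le.virtual_temperature(298.15, p, 101.3246) for p in (0.0, 1.0, 2.0, 3.0)]
        assert all(a < b for a, b in zip(tvs, tvs[1:]))
        assert all(tv >= 298.15 for tv in tvs)

    def test_vapor_exceeding_total_pressure_rejected(self):
        with pytest.raises(ValueError, match="pressure"):
            le.virtual_temperature(298.15, 102.0, 101.3246)


class TestVaporConcentrationDifference:
    def test_saturated_isothermal_limit(self):
        assert le.vapor_concentration_difference(298.15, 298.15, 1.0) == pytest.approx(
            0.0, abs=1e-15
        )

    def test_default_conditions(self):
        d = le.vapor_concentration_difference(298.15, 298.15, 0.5)
        assert d == pytest.approx(0.639, abs=0.003)

    def test_cold_leaf_in_saturated_air_forms_dew(self):
        assert le.vapor_concentration_difference(288.15, 298.15, 1.0) < 0.0


def test_unit_and_unitless_paths_agree(rng):
    """Tagged and untagged evaluation of every derived quantity coincide."""
    for _ in range(50):
        t_leaf = float(rng.uniform(270.0, 320.0))
        t_air = float(rng.uniform(278.0, 313.0))
        p = float(rng.uniform(80.0, 101.3246))
        rh = float(rng.uniform(0.1, 0.95))
        s_sw = float(rng.uniform(0.0, 1200.0))
        pairs = [
            (le.saturation_vapor_pressure(t_air),
             le.saturation_vapor_pressure(Quantity(t_air, "K")).m_as("kPa")),
            (le.latent_heat_vaporization(t_leaf),
             le.latent_heat_vaporization(Quantity(t_leaf, "K")).m_as("J/mol")),
            (le.dry_air_density(p, t_air),
             le.dry_air_density(Quantity(p * 1e3, "Pa"), Quantity(t_air, "K")).m_as("g/m^3")),
            (le.sky_temperature(t_air, s_sw),
             le.sky_temperature(Quantity(t_air, "K"), Quantity(s_sw, "W/m^2")).m_as("K")),
            (le.vapor_concentration_difference(t_leaf, t_air, rh),
             le.vapor_concentration_difference(
                 Quantity(t_leaf, "K"), Quantity(t_air, "K"), rh).m_as("mol/m^3")),
        ]
        for plain, tagged in pairs:
            assert tagged == pytest.approx(plain, rel=1e-10)


def test_continuity_in_temperature():
    """Derived quantities vary smoothly across the validity range."""
    eps = 1e-6
    for t in (250.0, 273.15, 298.15, 330.0):
        for f in (le.saturation_vapor_pressure, le.latent_heat_vaporization):
            assert f(t + eps) == pytest.approx(f(t), rel=1e-4)
    assert math.isfinite(le.vapor_concentration_difference(241.0, 339.0, 0.5))
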