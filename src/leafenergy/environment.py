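"""Derived environmental physics.

Everything the energy budget needs that is a function of the microclimate
alone (or of a candidate leaf temperature and the microclimate): saturation
vapour pressure, latent heat of vaporization, dry-air density, clear-sky
temperature and incident long-wave flux, temperature/pressure-scaled
diffusivities, virtual temperature, and the leaf–air water-vapour
concentration difference that drives transpiration.

All functions accept plain floats (in the canonical units stated per
argument) or unit-tagged Quantities; dimensions are checked at entry and the
result is tagged when any input was.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .parameters import (
    EnvironmentalParameters,
    PhysicalConstants,
    default_constants,
)
from .units import has_units, magnitude, wrap

__all__ = [
    "saturation_vapor_pressure",
    "air_vapor_pressure",
    "latent_heat_vaporization",
    "dry_air_density",
    "sky_temperature",
    "incident_longwave",
    "scale_diffusivity",
    "virtual_temperature",
    "vapor_concentration_difference",
    "DerivedEnvironment",
    "derive_environment",
    "T_VALID",
    "P_REF_KPA",
    "T_REF_K",
]

T_VALID = (240.0, 340.0)  # K, validity range of the vapour-pressure fits
P_REF_KPA = 101.3246      # reference pressure for the diffusivity scaling
T_REF_K = 273.15          # reference temperature (0 °C)

_GG_TS = 373.16  # steam-point temperature used by the Goff–Gratch fit


def _check_T(t: float) -> float:
    if not T_VALID[0] < t < T_VALID[1]:
        raise ValueError(
            f"temperature {t} K outside the validity range "
            f"({T_VALID[0]}, {T_VALID[1]}) K"
        )
    return t


def saturation_vapor_pressure(T) -> float:
    """Saturation vapour pressure over liquid water, kPa (Goff–Gratch).

    Parameters
    ----------
    T : float, K

    Strictly increasing in T; valid for 240 K < T < 340 K.
    """
    uq = has_units(T)
    t = _check_T(magnitude(T, "K"))
    x = _GG_TS / t
    log10_p_hpa = (
        -7.90298 * (x - 1.0)
        + 5.02808 * math.log10(x)
        - 1.3816e-7 * (10.0 ** (11.344 * (1.0 - t / _GG_TS)) - 1.0)
        + 8.1328e-3 * (10.0 ** (-3.49149 * (x - 1.0)) - 1.0)
        + math.log10(1013.246)
    )
    return wrap(10.0 ** log10_p_hpa / 10.0, "kPa", uq)


def air_vapor_pressure(p_sat, RH) -> float:
    """Water vapour pressure of the air, kPa: ``p_air = RH * p_sat``."""
    uq = has_units(p_sat, RH)
    rh = magnitude(RH, "1")
    if not 0.0 <= rh <= 1.0:
        raise ValueError(f"RH = {rh} outside [0, 1]")
    return wrap(rh * magnitude(p_sat, "kPa"), "kPa", uq)


def latent_heat_vaporization(T) -> float:
    """Molar latent heat of vaporization of water, J mol⁻¹.

    Linear in temperature, calibrated to 45.06 kJ mol⁻¹ at 0 °C and
    43.99 kJ mol⁻¹ at 25 °C (standard steam-table values); strictly
    decreasing in T.
    """
    uq = has_units(T)
    t = _check_T(magnitude(T, "K"))
    return wrap(45060.0 - 42.8 * (t - T_REF_K), "J/mol", uq)


def dry_air_density(P, T, R_air=287.058) -> float:
    """Density of dry air, g m⁻³, from the ideal-gas law.

    Parameters
    ----------
    P : float, kPa
    T : float, K
    R_air : float, J kg⁻¹ K⁻¹
        Specific gas constant of dry air.
    """
    uq = has_units(P, T, R_air)
    p_pa = magnitude(P, "kPa") * 1e3
    t = magnitude(T, "K")
    r_air = magnitude(R_air, "J/kg/K")
    if p_pa <= 0 or t <= 0:
        raise ValueError("pressure and temperature must be positive")
    return wrap(p_pa / (r_air * t) * 1e3, "g/m^3", uq)


def sky_temperature(T_air, S_sw) -> float:
    """Effective clear-sky radiative temperature, K.

    A clear sky radiates as a body colder than the air; the deficit scales
    with insolation: ``T_sky = T_air − 20 K × S_sw / (1000 W m⁻²)``, so the
    sky equals air temperature in the dark and is 20 K colder at full sun.
    Replaceable: pass any ``(T_air, S_sw) -> T_sky`` callable to the solver
    (e.g. a cloudy-sky model).
    """
    uq = has_units(T_air, S_sw)
    s = magnitude(S_sw, "W/m^2")
    if s < 0:
        raise ValueError(f"S_sw = {s} must be non-negative")
    return wrap(magnitude(T_air, "K") - 20.0 * s / 1000.0, "K", uq)


def incident_longwave(T_sky, T_air, sigma=5.67e-8) -> float:
    """Incident long-wave flux on the leaf (both surfaces), W m⁻².

    The sky (at ``T_sky``) irradiates the upper surface and the surroundings
    (at ``T_air``) the lower surface: ``S_lw = σ T_sky⁴ + σ T_air⁴``.
    """
    uq = has_units(T_sky, T_air, sigma)
    t_sky = magnitude(T_sky, "K")
    t_air = magnitude(T_air, "K")
    if t_sky <= 0 or t_air <= 0:
        raise ValueError("temperatures must be positive")
    s = magnitude(sigma, "W/m^2/K^4")
    return wrap(s * t_sky ** 4 + s * t_air ** 4, "W/m^2", uq)


def scale_diffusivity(D_0, T, P, eT=1.75) -> float:
    """Scale a 0 °C, sea-level diffusivity to temperature T and pressure P.

    ``D(T, P) = D_0 (T/273.15 K)^eT (101.3246 kPa / P)`` — the standard
    kinetic-theory temperature/pressure dependence of gaseous diffusion,
    applied identically to the heat, momentum and water-vapour
    diffusivities.
    """
    uq = has_units(D_0, T, P, eT)
    d0 = magnitude(D_0, "m^2/s")
    t = magnitude(T, "K")
    p = magnitude(P, "kPa")
    e = magnitude(eT, "1")
    if d0 <= 0 or t <= 0 or p <= 0:
        raise ValueError("diffusivity, temperature and pressure must be positive")
    return wrap(d0 * (t / T_REF_K) ** e * (P_REF_KPA / p), "m^2/s", uq)


def virtual_temperature(T, p, P, epsilon=0.622) -> float:
    """Virtual temperature of moist air, K.

    The temperature dry air would need to have the density of moist air at
    the same pressure: ``T_v = T / (1 − (1 − ε) p/P)`` with ``p`` the vapour
    pressure.  ``T_v ≥ T`` with equality only for dry air; buoyancy (free
    convection) is driven by virtual-temperature differences, so humidity
    gradients stir air even between surfaces at equal kinetic temperature.
    """
    uq = has_units(T, p, P, epsilon)
    t = magnitude(T, "K")
    pv = magnitude(p, "kPa")
    ptot = magnitude(P, "kPa")
    eps = magnitude(epsilon, "1")
    if pv < 0:
        raise ValueError(f"vapour pressure {pv} kPa must be non-negative")
    if pv >= ptot:
        raise ValueError(
            f"vapour pressure {pv} kPa must be below total pressure {ptot} kPa"
        )
    return wrap(t / (1.0 - (1.0 - eps) * (pv / ptot)), "K", uq)


def vapor_concentration_difference(T_leaf, T_air, RH, R=8.3144598) -> float:
    """Leaf-interior minus air water-vapour concentration, mol m⁻³.

    Assumes the leaf intercellular air space is saturated at ``T_leaf``:
    ``d_wv = p_sat(T_leaf)/(R T_leaf) − RH p_sat(T_air)/(R T_air)`` (pressures
    in Pa inside the ideal-gas conversion).  Positive drives evaporation;
    negative means condensation (dew) onto the leaf.
    """
    uq = has_units(T_leaf, T_air, RH, R)
    t_leaf = magnitude(T_leaf, "K")
    t_air = magnitude(T_air, "K")
    rh = magnitude(RH, "1")
    r = magnitude(R, "J/mol/K")
    p_leaf = saturation_vapor_pressure(t_leaf) * 1e3
    p_air = rh * saturation_vapor_pressure(t_air) * 1e3
    return wrap(p_leaf / (r * t_leaf) - p_air / (r * t_air), "mol/m^3", uq)


@dataclass(frozen=True)
class DerivedEnvironment:
    """Derived environmental quantities at one solver evaluation.

    ``p_sat`` and ``p_air`` are evaluated at air temperature; ``h_vap`` and
    ``d_wv`` at the (candidate) leaf temperature, since that is where the
    latent flux uses them.  All values are plain floats in the canonical
    units noted.
    """

    p_sat: float   # kPa, saturation vapour pressure at T_air
    p_air: float   # kPa, actual vapour pressure of the air
    h_vap: float   # J mol⁻¹, latent heat at T_leaf
    P_a: float     # g m⁻³, dry-air density at T_air
    T_sky: float   # K
    S_lw: float    # W m⁻²
    D_h: float     # m² s⁻¹
    D_m: float     # m² s⁻¹
    D_w: float     # m² s⁻¹
    d_wv: float    # mol m⁻³


def derive_environment(T_leaf, env: EnvironmentalParameters,
                       constants: PhysicalConstants | None = None,
                       units: bool = False,
                       sky_model=sky_temperature) -> DerivedEnvironment:
    """Compute every derived environmental quantity for one candidate T_leaf."""
    cons = constants if constants is not None else default_constants()
    if units:
        from .units import Quantity

        T_leaf = Quantity(magnitude(T_leaf, "K"), "K")
        P = Quantity(env.P, "kPa")
        T_air = Quantity(env.T_air, "K")
        S_sw = Quantity(env.S_sw, "W/m^2")
        RH = Quantity(env.RH, "1")
        sigma = Quantity(cons.sigma, "W/m^2/K^4")
        R = Quantity(cons.R, "J/mol/K")
        R_air = Quantity(cons.R_air, "J/kg/K")
        D_h0 = Quantity(cons.D_h0, "m^2/s")
        D_m0 = Quantity(cons.D_m0, "m^2/s")
        D_w0 = Quantity(cons.D_w0, "m^2/s")
    else:
        P, T_air, S_sw, RH = env.P, env.T_air, env.S_sw, env.RH
        sigma, R, R_air = cons.sigma, cons.R, cons.R_air
        D_h0, D_m0, D_w0 = cons.D_h0, cons.D_m0, cons.D_w0

    p_sat = saturation_vapor_pressure(T_air)
    p_air = air_vapor_pressure(p_sat, RH)
    T_sky = sky_model(T_air, S_sw)
    S_lw = incident_longwave(T_sky, T_air, sigma)
    return DerivedEnvironment(
        p_sat=magnitude(p_sat, "kPa"),
        p_air=magnitude(p_air, "kPa"),
        h_vap=magnitude(latent_heat_vaporization(T_leaf), "J/mol"),
        P_a=magnitude(dry_air_density(P, T_air, R_air), "g/m^3"),
        T_sky=magnitude(T_sky, "K"),
        S_lw=magnitude(S_lw, "W/m^2"),
        D_h=magnitude(scale_diffusivity(D_h0, T_air, P, cons.eT), "m^2/s"),
        D_m=magnitude(scale_diffusivity(D_m0, T_air, P, cons.eT), "m^2/s"),
        D_w=magnitude(scale_diffusivity(D_w0, T_air, P, cons.eT), "m^2/s"),
        d_wv=magnitude(vapor_concentration_difference(T_leaf, T_air, RH, R), "mol/m^3"),
    )
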