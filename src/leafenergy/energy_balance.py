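"""The leaf energy budget: flux components and the net balance.

At equilibrium the absorbed radiation equals the sum of the three losses,

    0 = R_abs − (S_r + H + L),

with R_abs the absorbed short- plus long-wave radiation, S_r the thermal
infrared emission from both surfaces, H the sensible heat flux and L the
latent heat flux (all W m⁻²).  :func:`net_energy_flux` evaluates the left
side at a candidate leaf temperature, re-deriving every temperature-dependent
quantity — emission, buoyancy via virtual temperature at the saturated leaf
surface, the leaf-interior vapour pressure, the latent heat — rather than
freezing them at air temperature (the isothermal shortcut some faster models
take).  The net flux is strictly decreasing in leaf temperature, which is
what makes the equilibrium unique and bracketable.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import nan

from . import boundary_layer as bl
from . import environment as envphys
from .parameters import (
    EnvironmentalParameters,
    LeafParameters,
    PhysicalConstants,
    default_constants,
    stomatal_ratio,
)
from .units import Quantity, has_units, magnitude, wrap

__all__ = [
    "absorbed_radiation",
    "emitted_radiation",
    "sensible_heat_flux",
    "transpiration_rate",
    "latent_heat_flux",
    "net_energy_flux",
    "energy_balance_components",
    "EnergyFluxes",
]


def absorbed_radiation(abs_s, abs_l, r, S_sw, S_lw) -> float:
    """Radiation absorbed by the leaf, W m⁻².

    Direct shortwave hits the upper surface, ground-reflected shortwave
    (albedo ``r``) the lower, and ``S_lw`` carries the long-wave load from
    sky and surroundings:  ``R_abs = abs_s (1 + r) S_sw + abs_l S_lw``.
    """
    uq = has_units(abs_s, abs_l, r, S_sw, S_lw)
    a_s = magnitude(abs_s, "1")
    a_l = magnitude(abs_l, "1")
    rr = magnitude(r, "1")
    for name, v in (("abs_s", a_s), ("abs_l", a_l), ("r", rr)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} = {v} outside [0, 1]")
    s_sw = magnitude(S_sw, "W/m^2")
    s_lw = magnitude(S_lw, "W/m^2")
    if s_sw < 0 or s_lw < 0:
        raise ValueError("radiative fluxes must be non-negative")
    return wrap(a_s * (1.0 + rr) * s_sw + a_l * s_lw, "W/m^2", uq)


def emitted_radiation(abs_l, T_leaf, sigma=5.67e-8) -> float:
    """Thermal infrared loss from both leaf surfaces, W m⁻².

    ``S_r = 2 abs_l σ T_leaf⁴`` — long-wave emissivity equals long-wave
    absorptivity (Kirchhoff's law).
    """
    uq = has_units(abs_l, T_leaf, sigma)
    t = magnitude(T_leaf, "K")
    if t <= 0:
        raise ValueError("T_leaf must be positive")
    a_l = magnitude(abs_l, "1")
    s = magnitude(sigma, "W/m^2/K^4")
    return wrap(2.0 * a_l * s * t ** 4, "W/m^2", uq)


def sensible_heat_flux(P_a, c_p, g_h, T_leaf, T_air) -> float:
    """Convective heat exchange, W m⁻² (positive = loss from the leaf).

    ``H = P_a c_p g_h (T_leaf − T_air)`` with ``P_a`` the dry-air density
    (g m⁻³), ``c_p`` the heat capacity of air (J g⁻¹ K⁻¹) and ``g_h`` the
    total two-surface boundary-layer conductance to heat (m s⁻¹).
    """
    uq = has_units(P_a, c_p, g_h, T_leaf, T_air)
    pa = magnitude(P_a, "g/m^3")
    cp = magnitude(c_p, "J/g/K")
    gh = magnitude(g_h, "m/s")
    if pa < 0 or gh < 0:
        raise ValueError("P_a and g_h must be non-negative")
    return wrap(pa * cp * gh * (magnitude(T_leaf, "K") - magnitude(T_air, "K")),
                "W/m^2", uq)


def transpiration_rate(g_tw, d_wv) -> float:
    """Transpiration, mol m⁻² s⁻¹: ``E = g_tw d_wv``.

    Negative when the air is supersaturated relative to the leaf —
    condensation (dew), an energy gain.
    """
    uq = has_units(g_tw, d_wv)
    gtw = magnitude(g_tw, "m/s")
    if gtw < 0:
        raise ValueError("g_tw must be non-negative")
    return wrap(gtw * magnitude(d_wv, "mol/m^3"), "mol/m^2/s", uq)


def latent_heat_flux(h_vap, E) -> float:
    """Latent heat flux, W m⁻²: ``L = h_vap E`` (sign follows E)."""
    uq = has_units(h_vap, E)
    hv = magnitude(h_vap, "J/mol")
    if hv <= 0:
        raise ValueError("h_vap must be positive")
    return wrap(hv * magnitude(E, "mol/m^2/s"), "W/m^2", uq)


@dataclass(frozen=True)
class EnergyFluxes:
    """Flux breakdown at one candidate leaf temperature (all W m⁻² but E)."""

    R_abs: float
    S_r: float
    H: float
    L: float
    E: float    # mol m⁻² s⁻¹
    net: float  # R_abs − (S_r + H + L)


def energy_balance_components(
    T_leaf,
    leaf: LeafParameters,
    env: EnvironmentalParameters,
    constants: PhysicalConstants | None = None,
    units: bool = False,
    sky_model=envphys.sky_temperature,
):
    """Evaluate the full energy budget at a candidate leaf temperature.

    Returns ``(EnergyFluxes, SurfaceConductances, DerivedEnvironment)``.
    With ``units=True`` every inter-function value is tagged with its unit
    and dimension-checked (slower; numerically equivalent).
    """
    cons = constants if constants is not None else default_constants()
    t_leaf = magnitude(T_leaf, "K")

    derived = envphys.derive_environment(t_leaf, env, cons, units=units,
                                         sky_model=sky_model)

    if units:
        q = Quantity
        T_leaf_q = q(t_leaf, "K")
        T_air = q(env.T_air, "K")
        P = q(env.P, "kPa")
        u = q(env.u, "m/s")
        d = q(leaf.d, "m")
        g_sw = q(leaf.g_sw, "umol/m^2/s/Pa")
        g_uw = q(leaf.g_uw, "umol/m^2/s/Pa")
        S_sw = q(env.S_sw, "W/m^2")
        sigma = q(cons.sigma, "W/m^2/K^4")
        G = q(cons.G, "m/s^2")
        R = q(cons.R, "J/mol/K")
        c_p = q(cons.c_p, "J/g/K")
        D_h = q(derived.D_h, "m^2/s")
        D_m = q(derived.D_m, "m^2/s")
        D_w = q(derived.D_w, "m^2/s")
        P_a = q(derived.P_a, "g/m^3")
        p_air = q(derived.p_air, "kPa")
        S_lw = q(derived.S_lw, "W/m^2")
        h_vap = q(derived.h_vap, "J/mol")
        d_wv = q(derived.d_wv, "mol/m^3")
    else:
        T_leaf_q, T_air, P, u = t_leaf, env.T_air, env.P, env.u
        d, g_sw, g_uw, S_sw = leaf.d, leaf.g_sw, leaf.g_uw, env.S_sw
        sigma, G, R, c_p = cons.sigma, cons.G, cons.R, cons.c_p
        D_h, D_m, D_w = derived.D_h, derived.D_m, derived.D_w
        P_a, p_air, S_lw = derived.P_a, derived.p_air, derived.S_lw
        h_vap, d_wv = derived.h_vap, derived.d_wv

    # buoyancy from virtual temperatures (saturated air at the leaf surface)
    p_sat_leaf = envphys.saturation_vapor_pressure(T_leaf_q)
    T_v_air = envphys.virtual_temperature(T_air, p_air, P, cons.epsilon)
    T_v_leaf = envphys.virtual_temperature(T_leaf_q, p_sat_leaf, P, cons.epsilon)
    leaf_warmer = magnitude(T_v_leaf, "K") >= magnitude(T_v_air, "K")

    Re = bl.reynolds_number(u, d, D_m)
    Gr = bl.grashof_number(d, T_v_leaf, T_v_air, D_m, G)
    re_f = magnitude(Re, "1")
    ar = bl.archimedes_number(Gr, Re) if re_f > 0 else nan
    regime = bl.classify_convection(Gr, Re)

    Nu_u = bl.nusselt_number(Re, Gr, cons, "upper", leaf_warmer)
    Nu_l = bl.nusselt_number(Re, Gr, cons, "lower", leaf_warmer)
    Sh_u = bl.sherwood_number(Re, Gr, cons, "upper", leaf_warmer)
    Sh_l = bl.sherwood_number(Re, Gr, cons, "lower", leaf_warmer)

    g_h_u = bl.boundary_conductance(Nu_u, D_h, d)
    g_h_l = bl.boundary_conductance(Nu_l, D_h, d)
    g_bw_u = bl.boundary_conductance(Sh_u, D_w, d)
    g_bw_l = bl.boundary_conductance(Sh_l, D_w, d)

    SR = stomatal_ratio(leaf.logit_sr)
    # molar→velocity conversion at air temperature
    g_tw = bl.total_water_conductance(g_sw, g_uw, SR, g_bw_u, g_bw_l, T_air, R)

    conductances = bl.SurfaceConductances(
        Re=re_f,
        Gr=magnitude(Gr, "1"),
        Ar=ar,
        regime=regime,
        Nu_upper=float(Nu_u),
        Nu_lower=float(Nu_l),
        Sh_upper=float(Sh_u),
        Sh_lower=float(Sh_l),
        g_h_upper=magnitude(g_h_u, "m/s"),
        g_h_lower=magnitude(g_h_l, "m/s"),
        g_bw_upper=magnitude(g_bw_u, "m/s"),
        g_bw_lower=magnitude(g_bw_l, "m/s"),
        g_tw=magnitude(g_tw, "m/s"),
    )

    R_abs = absorbed_radiation(leaf.abs_s, leaf.abs_l, env.r, S_sw, S_lw)
    S_r = emitted_radiation(leaf.abs_l, T_leaf_q, sigma)
    H = sensible_heat_flux(P_a, c_p, g_h_u + g_h_l, T_leaf_q, T_air)
    E = transpiration_rate(g_tw, d_wv)
    L = latent_heat_flux(h_vap, E)

    r_abs = magnitude(R_abs, "W/m^2")
    s_r = magnitude(S_r, "W/m^2")
    h = magnitude(H, "W/m^2")
    ll = magnitude(L, "W/m^2")
    fluxes = EnergyFluxes(
        R_abs=r_abs, S_r=s_r, H=h, L=ll,
        E=magnitude(E, "mol/m^2/s"),
        net=r_abs - (s_r + h + ll),
    )
    return fluxes, conductances, derived


def net_energy_flux(
    T_leaf,
    leaf: LeafParameters,
    env: EnvironmentalParameters,
    constants: PhysicalConstants | None = None,
    units: bool = False,
    sky_model=envphys.sky_temperature,
) -> EnergyFluxes:
    """Net energy flux at a candidate leaf temperature, with the breakdown.

    ``fluxes.net = R_abs − (S_r + H + L)``; zero at equilibrium, positive
    when the candidate temperature is too cold, negative when too warm.
    """
    fluxes, _, _ = energy_balance_components(
        T_leaf, leaf, env, constants, units=units, sky_model=sky_model
    )
    return fluxes
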