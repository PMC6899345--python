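"""Boundary-layer transport: dimensionless numbers and conductances.

Heat and water vapour cross the layer of still air hugging each leaf surface
by diffusion; how thick that layer is depends on wind (forced convection,
indexed by the Reynolds number Re) and on buoyancy (free convection, indexed
by the Grashof number Gr computed from virtual temperatures).  Empirical
flat-plate correlations turn Re and Gr into Nusselt (heat) and Sherwood
(mass) numbers, mixed as ``(forced^m + free^m)^(1/m)``, and those into
per-surface conductances ``g = D·Nu/d``.  The Archimedes number Ar = Gr/Re²
classifies the regime: forced (Ar < 0.1), mixed (0.1 ≤ Ar ≤ 10), free
(Ar > 10).

The upper and lower surfaces are treated separately: free convection is
damped (coefficient × ``free_asymmetry``) on the stably-stratified side —
below a leaf warmer than the air, above one cooler — and the stomatal ratio
partitions stomatal conductance between the surfaces.
"""

from __future__ import annotations

from dataclasses import dataclass

from .parameters import PhysicalConstants, default_constants
from .units import has_units, magnitude, wrap

__all__ = [
    "reynolds_number",
    "grashof_number",
    "archimedes_number",
    "classify_convection",
    "nusselt_number",
    "sherwood_number",
    "molar_to_velocity",
    "boundary_conductance",
    "total_water_conductance",
    "SurfaceConductances",
    "AR_FORCED_MAX",
    "AR_FREE_MIN",
]

AR_FORCED_MAX = 0.1
AR_FREE_MIN = 10.0


def reynolds_number(u, d, D_m) -> float:
    """Re = u·d/D_m — inertial vs. viscous forces (forced convection).

    Parameters: ``u`` m s⁻¹ wind speed, ``d`` m characteristic dimension,
    ``D_m`` m² s⁻¹ momentum diffusivity.
    """
    uq = has_units(u, d, D_m)
    uu = magnitude(u, "m/s")
    dd = magnitude(d, "m")
    dm = magnitude(D_m, "m^2/s")
    if dd <= 0 or dm <= 0:
        raise ValueError("d and D_m must be positive")
    if uu < 0:
        raise ValueError("wind speed must be non-negative")
    return wrap(uu * dd / dm, "1", uq)


def grashof_number(d, T_v_leaf, T_v_air, D_m, G=9.8) -> float:
    """Gr = G·d³·|ΔT_v| / (T_v_air·D_m²) — buoyant vs. viscous forces.

    Uses virtual temperatures, so a humidity difference alone (lighter moist
    air at the evaporating surface) drives free convection even at equal
    kinetic temperatures.
    """
    uq = has_units(d, T_v_leaf, T_v_air, D_m, G)
    dd = magnitude(d, "m")
    tv_leaf = magnitude(T_v_leaf, "K")
    tv_air = magnitude(T_v_air, "K")
    dm = magnitude(D_m, "m^2/s")
    g = magnitude(G, "m/s^2")
    if dd <= 0 or dm <= 0 or tv_air <= 0:
        raise ValueError("d, D_m and T_v_air must be positive")
    return wrap(g * dd ** 3 * abs(tv_leaf - tv_air) / (tv_air * dm ** 2), "1", uq)


def archimedes_number(Gr, Re) -> float:
    """Ar = Gr/Re², the free-to-forced convection ratio.  Requires Re > 0."""
    gr = magnitude(Gr, "1")
    re = magnitude(Re, "1")
    if re <= 0:
        raise ValueError("Ar is undefined at Re = 0 (pure free convection)")
    return gr / re ** 2


def classify_convection(Gr, Re) -> str:
    """Label the convection regime: ``"forced"``, ``"mixed"`` or ``"free"``.

    Still air (Re = 0) is free convection by definition; otherwise the
    Archimedes number is compared with the 0.1 and 10 thresholds.
    """
    re = magnitude(Re, "1")
    if re == 0:
        return "free"
    ar = archimedes_number(Gr, Re)
    if ar < AR_FORCED_MAX:
        return "forced"
    if ar > AR_FREE_MIN:
        return "free"
    return "mixed"


def _forced_component(re: float, cons: PhysicalConstants) -> float:
    if re > cons.Re_crit:
        a, b = cons.nu_coefs["forced_turbulent"]
    else:
        a, b = cons.nu_coefs["forced_laminar"]
    return a * re ** b if re > 0 else 0.0


def _free_component(gr: float, cons: PhysicalConstants, surface: str,
                    leaf_warmer: bool) -> float:
    c, dd = cons.nu_coefs["free"]
    # damp buoyancy on the stably-stratified side of the plate
    if (surface == "upper") != leaf_warmer:
        c = c * cons.free_asymmetry
    return c * gr ** dd if gr > 0 else 0.0


def _mixed(re: float, gr: float, cons: PhysicalConstants, surface: str,
           leaf_warmer: bool) -> float:
    forced = _forced_component(re, cons)
    free = _free_component(gr, cons, surface, leaf_warmer)
    if forced == 0.0:
        return free
    if free == 0.0:
        return forced
    m = cons.mixing_exponent
    return (forced ** m + free ** m) ** (1.0 / m)


def nusselt_number(Re, Gr, constants: PhysicalConstants | None = None,
                   surface: str = "upper", leaf_warmer: bool = True) -> float:
    """Mixed-convection Nusselt number for one leaf surface.

    Forced: ``Nu = a·Re^b`` with (a, b) switching from the laminar to the
    turbulent correlation for Re > Re_crit (a jump — the laminar→turbulent
    transition).  Free: ``Nu = c·Gr^d``, with ``c`` damped by the asymmetry
    factor on the stably-stratified surface.  Mixed:
    ``Nu = (Nu_forced^m + Nu_free^m)^(1/m)``, which collapses exactly to the
    pure regime when the other driver vanishes.
    """
    cons = constants if constants is not None else default_constants()
    if surface not in ("upper", "lower"):
        raise ValueError(f"surface must be 'upper' or 'lower', got {surface!r}")
    re = magnitude(Re, "1")
    gr = magnitude(Gr, "1")
    if re < 0 or gr < 0:
        raise ValueError("Re and Gr must be non-negative")
    return _mixed(re, gr, cons, surface, leaf_warmer)


def sherwood_number(Re, Gr, constants: PhysicalConstants | None = None,
                    surface: str = "upper", leaf_warmer: bool = True) -> float:
    """Mixed-convection Sherwood number (mass-transfer analogue of Nu).

    Shares the Nusselt correlation coefficient table; see
    :func:`nusselt_number`.
    """
    return nusselt_number(Re, Gr, constants, surface, leaf_warmer)


def molar_to_velocity(g, T, R=8.3144598) -> float:
    """Convert a molar conductance to a velocity conductance, m s⁻¹.

    ``g_vel = g × 10⁻⁶ × R × T`` via the ideal gas law, with ``g`` in
    µmol m⁻² s⁻¹ Pa⁻¹ and ``T`` in K.
    """
    uq = has_units(g, T, R)
    gm = magnitude(g, "umol/m^2/s/Pa")
    t = magnitude(T, "K")
    r = magnitude(R, "J/mol/K")
    if gm < 0:
        raise ValueError("conductance must be non-negative")
    return wrap(gm * 1e-6 * r * t, "m/s", uq)


def boundary_conductance(Nu, D, d) -> float:
    """Per-surface boundary-layer conductance, m s⁻¹: ``g = D·Nu/d``.

    With the heat diffusivity and Nusselt number this is ``g_h``; with the
    water-vapour diffusivity and Sherwood number, ``g_bw``.
    """
    uq = has_units(Nu, D, d)
    dd = magnitude(d, "m")
    if dd <= 0:
        raise ValueError("d must be positive")
    return wrap(magnitude(D, "m^2/s") * magnitude(Nu, "1") / dd, "m/s", uq)


def _series(x: float, y: float) -> float:
    # conductances in series; a sealed path (0) carries no flux
    if x == 0.0 or y == 0.0:
        return 0.0
    return 1.0 / (1.0 / x + 1.0 / y)


def total_water_conductance(g_sw, g_uw, SR, g_bw_upper, g_bw_lower,
                            T, R=8.3144598) -> float:
    """Total leaf conductance to water vapour, m s⁻¹.

    The stomatal ratio SR assigns ``SR·g_sw`` to the upper surface and
    ``(1−SR)·g_sw`` to the lower; cuticular conductance is split equally.
    Each surface's (stomatal + cuticular) conductance, converted to velocity
    units at temperature ``T``, acts in series with that surface's
    boundary-layer conductance, and the two surfaces add in parallel.
    """
    uq = has_units(g_sw, g_uw, SR, g_bw_upper, g_bw_lower, T)
    gsw = magnitude(g_sw, "umol/m^2/s/Pa")
    guw = magnitude(g_uw, "umol/m^2/s/Pa")
    sr = magnitude(SR, "1")
    if not 0.0 <= sr <= 1.0:
        raise ValueError(f"SR = {sr} outside [0, 1]")
    if gsw < 0 or guw < 0:
        raise ValueError("conductances must be non-negative")
    t = magnitude(T, "K")
    r = magnitude(R, "J/mol/K")
    upper = _series(
        molar_to_velocity(sr * gsw + guw / 2.0, t, r),
        magnitude(g_bw_upper, "m/s"),
    )
    lower = _series(
        molar_to_velocity((1.0 - sr) * gsw + guw / 2.0, t, r),
        magnitude(g_bw_lower, "m/s"),
    )
    return wrap(upper + lower, "m/s", uq)


@dataclass(frozen=True)
class SurfaceConductances:
    """Dimensionless numbers and conductances at one solver evaluation.

    Per-surface values are kept separately; ``g_h`` and ``g_bw`` sum the two
    parallel surfaces, while ``Nu`` and ``Sh`` report the two-surface mean
    (so ``g_h = 2·D_h·Nu/d``).
    """

    Re: float
    Gr: float
    Ar: float          # NaN when Re = 0
    regime: str
    Nu_upper: float
    Nu_lower: float
    Sh_upper: float
    Sh_lower: float
    g_h_upper: float   # m s⁻¹
    g_h_lower: float
    g_bw_upper: float
    g_bw_lower: float
    g_tw: float        # m s⁻¹, total conductance to water vapour

    @property
    def Nu(self) -> float:
        return 0.5 * (self.Nu_upper + self.Nu_lower)

    @property
    def Sh(self) -> float:
        return 0.5 * (self.Sh_upper + self.Sh_lower)

    @property
    def g_h(self) -> float:
        """Total (two-surface) boundary-layer conductance to heat, m s⁻¹."""
        return self.g_h_upper + self.g_h_lower

    @property
    def g_bw(self) -> float:
        """Total (two-surface) boundary-layer conductance to water, m s⁻¹."""
        return self.g_bw_upper + self.g_bw_lower
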