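"""Parameter sets for the leaf energy-budget model.

Three groups of inputs drive the model:

* :class:`LeafParameters` — traits of the leaf itself: characteristic
  dimension ``d`` (the diameter of the largest circle inscribable in the leaf
  margin), short- and long-wave absorptivities, stomatal and cuticular
  conductances to water vapour, and the stomatal ratio (stored on the logit
  scale).
* :class:`EnvironmentalParameters` — the microclimate: pressure, albedo,
  relative humidity, solar flux, air temperature, wind speed.
* :class:`PhysicalConstants` — physical constants and the empirical
  convection-correlation coefficients, all user-overridable.

Fields may be given as plain floats in the canonical units documented per
field, or as :class:`~leafenergy.units.Quantity` objects in any compatible
unit (``d=Quantity(10, "cm")`` is stored as 0.1 m).  Validation distinguishes
hard physical bounds (errors) from merely unusual values (warnings).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, fields
from typing import Iterable, Mapping, Sequence

from .units import Quantity, magnitude

__all__ = [
    "LeafParameters",
    "EnvironmentalParameters",
    "PhysicalConstants",
    "ParameterGrid",
    "default_leaf",
    "default_environment",
    "default_constants",
    "stomatal_ratio",
    "logit",
    "validate",
    "expand_grid",
    "LEAF_UNITS",
    "ENV_UNITS",
    "LEAF_ALIASES",
    "ENV_ALIASES",
]

# canonical unit per field (the unit a bare float is interpreted in)
LEAF_UNITS = {
    "d": "m",
    "abs_s": "1",
    "abs_l": "1",
    "g_sw": "umol/m^2/s/Pa",
    "g_uw": "umol/m^2/s/Pa",
    "logit_sr": "1",
}
ENV_UNITS = {
    "P": "kPa",
    "r": "1",
    "RH": "1",
    "S_sw": "W/m^2",
    "T_air": "K",
    "u": "m/s",
}

# I/O column names (the conventional symbols used in tabular output) → field
LEAF_ALIASES = {
    "leafsize": "d",
    "abs_s": "abs_s",
    "abs_l": "abs_l",
    "g_sw": "g_sw",
    "g_uw": "g_uw",
    "logit_sr": "logit_sr",
}
ENV_ALIASES = {
    "P": "P",
    "r": "r",
    "RH": "RH",
    "S_sw": "S_sw",
    "T_air": "T_air",
    "wind": "u",
}
LEAF_COLUMNS = {v: k for k, v in LEAF_ALIASES.items()}
ENV_COLUMNS = {v: k for k, v in ENV_ALIASES.items()}


def stomatal_ratio(logit_sr: float) -> float:
    """Inverse-logit: fraction of stomatal conductance on the upper surface.

    SR = 1/(1 + exp(-logit_sr)); SR = 0.5 is amphistomatous, SR → 0
    hypostomatous (all stomata on the lower surface), SR → 1 hyperstomatous.
    """
    x = float(logit_sr)
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def logit(sr: float) -> float:
    """Logit transform of a stomatal ratio in (0, 1)."""
    sr = float(sr)
    if not 0.0 < sr < 1.0:
        raise ValueError(f"stomatal ratio must lie strictly in (0, 1), got {sr}")
    return math.log(sr / (1.0 - sr))


def _coerce(value, unit: str, name: str) -> float:
    try:
        return magnitude(value, unit)
    except Exception as exc:
        raise ValueError(f"field {name!r}: {exc}") from exc


@dataclass(frozen=True)
class LeafParameters:
    """Leaf trait inputs.

    Parameters
    ----------
    d : float, m
        Characteristic leaf dimension.
    abs_s, abs_l : float, dimensionless
        Absorptivity of short-wave (0.3–4 µm) and long-wave (4–80 µm)
        radiation.  Long-wave emissivity equals ``abs_l`` (Kirchhoff).
    g_sw, g_uw : float, µmol m⁻² s⁻¹ Pa⁻¹
        Stomatal and cuticular conductance to water vapour (molar units).
    logit_sr : float
        Stomatal ratio on the logit scale; ``stomatal_ratio(logit_sr)`` is
        the fraction of stomatal conductance on the upper (adaxial) surface.
    """

    d: float = 0.1
    abs_s: float = 0.5
    abs_l: float = 0.97
    g_sw: float = 5.0
    g_uw: float = 0.1
    logit_sr: float = 0.0

    def __post_init__(self):
        for f in fields(self):
            object.__setattr__(
                self, f.name, _coerce(getattr(self, f.name), LEAF_UNITS[f.name], f.name)
            )

    @property
    def sr(self) -> float:
        """Stomatal ratio on the natural (0, 1) scale."""
        return stomatal_ratio(self.logit_sr)

    @classmethod
    def with_stomatal_ratio(cls, sr: float, **kwargs) -> "LeafParameters":
        """Construct with the stomatal ratio given on the (0, 1) scale."""
        return cls(logit_sr=logit(sr), **kwargs)


@dataclass(frozen=True)
class EnvironmentalParameters:
    """Microclimate inputs.

    Parameters
    ----------
    P : float, kPa
        Atmospheric pressure.
    r : float, dimensionless
        Ground reflectance (albedo) for short-wave irradiance.
    RH : float, fraction
        Relative humidity of the air.
    S_sw : float, W m⁻²
        Incident short-wave (solar) radiation flux density.
    T_air : float, K
        Air temperature.
    u : float, m s⁻¹
        Wind speed.
    """

    P: float = 101.3246
    r: float = 0.2
    RH: float = 0.5
    S_sw: float = 1000.0
    T_air: float = 298.15
    u: float = 2.0

    def __post_init__(self):
        for f in fields(self):
            object.__setattr__(
                self, f.name, _coerce(getattr(self, f.name), ENV_UNITS[f.name], f.name)
            )


def _default_nu_coefs() -> dict:
    # flat-plate correlations: Nu = a Re^b (forced), Nu = c Gr^d (free)
    return {
        "forced_laminar": (0.6, 0.5),
        "forced_turbulent": (0.032, 0.8),
        "free": (0.5, 0.25),
    }


@dataclass(frozen=True)
class PhysicalConstants:
    """Physical constants and convection-correlation coefficients.

    All defaults are standard values; every field can be overridden, so users
    with alternative boundary-layer correlations can substitute their own
    ``nu_coefs``, critical Reynolds number, mixing exponent or asymmetry
    factor without touching any other code.

    Attributes
    ----------
    nu_coefs : dict
        ``{"forced_laminar": (a, b), "forced_turbulent": (a, b), "free": (c, d)}``
        for Nu = a·Re^b (forced) and Nu = c·Gr^d (free); shared by the
        Sherwood number.
    c_p : float, J g⁻¹ K⁻¹ — heat capacity of air.
    D_h0, D_m0, D_w0 : float, m² s⁻¹ — diffusivities of heat, momentum and
        water vapour in air at 0 °C and 101.3246 kPa.
    epsilon : float — ratio of water to dry-air molar masses.
    eT : float — exponent of the temperature dependence of diffusion.
    G : float, m s⁻² — gravitational acceleration.
    R : float, J mol⁻¹ K⁻¹ — ideal gas constant.
    R_air : float, J kg⁻¹ K⁻¹ — specific gas constant of dry air.
    sigma : float, W m⁻² K⁻⁴ — Stefan–Boltzmann constant.
    Re_crit : float — laminar→turbulent transition Reynolds number.
    mixing_exponent : float — m in Nu = (Nu_forced^m + Nu_free^m)^(1/m).
    free_asymmetry : float — factor applied to the free-convection
        coefficient on the stably-stratified side of the leaf (below a warm
        leaf / above a cool one).
    """

    nu_coefs: dict = field(default_factory=_default_nu_coefs)
    c_p: float = 1.01
    D_h0: float = 19.0e-6
    D_m0: float = 13.3e-6
    D_w0: float = 21.2e-6
    epsilon: float = 0.622
    eT: float = 1.75
    G: float = 9.8
    R: float = 8.3144598
    R_air: float = 287.058
    sigma: float = 5.67e-8
    Re_crit: float = 4000.0
    mixing_exponent: float = 3.5
    free_asymmetry: float = 0.5

    _UNITS = {
        "c_p": "J/g/K",
        "D_h0": "m^2/s",
        "D_m0": "m^2/s",
        "D_w0": "m^2/s",
        "epsilon": "1",
        "eT": "1",
        "G": "m/s^2",
        "R": "J/mol/K",
        "R_air": "J/kg/K",
        "sigma": "W/m^2/K^4",
        "Re_crit": "1",
        "mixing_exponent": "1",
        "free_asymmetry": "1",
    }

    def __post_init__(self):
        for name, unit in self._UNITS.items():
            object.__setattr__(self, name, _coerce(getattr(self, name), unit, name))
        coefs = dict(self.nu_coefs)
        for key in ("forced_laminar", "forced_turbulent", "free"):
            if key not in coefs:
                raise ValueError(f"field 'nu_coefs': missing regime {key!r}")
            a, b = coefs[key]
            coefs[key] = (float(a), float(b))
        object.__setattr__(self, "nu_coefs", coefs)


def default_leaf() -> LeafParameters:
    """Default leaf traits: d = 0.1 m, abs_s = 0.5, abs_l = 0.97,
    g_sw = 5 and g_uw = 0.1 µmol m⁻² s⁻¹ Pa⁻¹, SR = 0.5."""
    return LeafParameters()


def default_environment() -> EnvironmentalParameters:
    """Default microclimate: sea-level pressure, albedo 0.2, RH 50 %,
    full sun (1000 W m⁻²), 25 °C air, 2 m s⁻¹ wind."""
    return EnvironmentalParameters()


def default_constants() -> PhysicalConstants:
    return PhysicalConstants()


# hard physical bounds: (low, high, low_inclusive, high_inclusive)
_HARD = {
    LeafParameters: {
        "d": (0.0, math.inf, False, False),
        "abs_s": (0.0, 1.0, True, True),
        "abs_l": (0.0, 1.0, True, True),
        "g_sw": (0.0, math.inf, True, False),
        "g_uw": (0.0, math.inf, True, False),
        "logit_sr": (-math.inf, math.inf, False, False),
    },
    EnvironmentalParameters: {
        "P": (0.0, math.inf, False, False),
        "r": (0.0, 1.0, True, True),
        "RH": (0.0, 1.0, True, True),
        "S_sw": (0.0, math.inf, True, False),
        "T_air": (0.0, math.inf, False, False),
        "u": (0.0, math.inf, True, False),
    },
}

# plausible field ranges; values outside trigger a warning, not an error
_REASONABLE = {
    LeafParameters: {
        "d": (0.001, 1.0),
        "abs_s": (0.2, 0.9),
        "abs_l": (0.9, 1.0),
        "g_sw": (0.0, 20.0),
        "g_uw": (0.0, 1.0),
        "logit_sr": (-6.0, 6.0),
    },
    EnvironmentalParameters: {
        "P": (50.0, 110.0),
        "r": (0.05, 0.5),
        "RH": (0.05, 1.0),
        "S_sw": (0.0, 1500.0),
        "T_air": (265.0, 320.0),
        "u": (0.0, 15.0),
    },
}


def validate(params):
    """Check invariants of a parameter set; return it unchanged if valid.

    Raises ``ValueError`` naming the offending field for physically
    impossible or non-finite values; emits a warning for values outside the
    plausible ranges.  Idempotent: ``validate(validate(x))`` is ``x``.
    """
    cls = type(params)
    if isinstance(params, PhysicalConstants):
        for name in PhysicalConstants._UNITS:
            v = getattr(params, name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"field {name!r} must be finite and positive, got {v}")
        return params
    if cls not in _HARD:
        raise TypeError(f"cannot validate object of type {cls.__name__}")
    for name, (lo, hi, lo_inc, hi_inc) in _HARD[cls].items():
        v = getattr(params, name)
        if not math.isfinite(v):
            raise ValueError(f"field {name!r} must be finite, got {v}")
        ok_lo = v >= lo if lo_inc else v > lo
        ok_hi = v <= hi if hi_inc else v < hi
        if not (ok_lo and ok_hi):
            raise ValueError(
                f"field {name!r} = {v} outside the physical range "
                f"{'[' if lo_inc else '('}{lo}, {hi}{']' if hi_inc else ')'}"
            )
    for name, (lo, hi) in _REASONABLE[cls].items():
        v = getattr(params, name)
        if not lo <= v <= hi:
            warnings.warn(
                f"field {name!r} = {v} is outside the plausible range "
                f"[{lo}, {hi}]; results may be unrealistic",
                stacklevel=2,
            )
    return params


@dataclass(frozen=True)
class ParameterGrid:
    """Ordered Cartesian product of leaf × environment parameter sets."""

    rows: tuple
    constants: PhysicalConstants = field(default_factory=PhysicalConstants)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def __getitem__(self, i):
        return self.rows[i]


def _resolve_lists(values: Mapping | None, aliases: Mapping[str, str],
                   units: Mapping[str, str], defaults) -> dict:
    values = dict(values or {})
    out = {}
    for key, val in values.items():
        name = aliases.get(key, key)
        if name not in units:
            raise ValueError(f"unknown parameter key {key!r}")
        if isinstance(val, (str, bytes)):
            raise ValueError(f"field {key!r}: expected a number or list, got {val!r}")
        if isinstance(val, (Sequence,)) and not isinstance(val, Quantity):
            seq = list(val)
        elif isinstance(val, Iterable) and not isinstance(val, Quantity):
            seq = list(val)
        else:
            seq = [val]
        if not seq:
            raise ValueError(f"field {key!r}: empty value list")
        out[name] = seq
    for name in units:
        out.setdefault(name, [getattr(defaults, name)])
    # declaration order
    return {name: out[name] for name in units}


def expand_grid(leaf: Mapping | None = None, env: Mapping | None = None,
                constants: PhysicalConstants | None = None) -> ParameterGrid:
    """Cross scalar-or-list leaf and environment values into a grid.

    Keys may be field names (``d``, ``u``) or the tabular column names
    (``leafsize``, ``wind``).  Rows are emitted in deterministic row-major
    order over the fields in declaration order (leaf fields first, the last
    field varying fastest); absent fields take their default value.  Every
    row is validated.
    """
    leaf_lists = _resolve_lists(leaf, LEAF_ALIASES, LEAF_UNITS, default_leaf())
    env_lists = _resolve_lists(env, ENV_ALIASES, ENV_UNITS, default_environment())
    constants = validate(constants if constants is not None else default_constants())
    names = list(leaf_lists) + list(env_lists)
    n_leaf = len(leaf_lists)
    rows = []
    for combo in itertools.product(*leaf_lists.values(), *env_lists.values()):
        lp = LeafParameters(**dict(zip(names[:n_leaf], combo[:n_leaf])))
        ep = EnvironmentalParameters(**dict(zip(names[n_leaf:], combo[n_leaf:])))
        rows.append((validate(lp), validate(ep)))
    return ParameterGrid(rows=tuple(rows), constants=constants)
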