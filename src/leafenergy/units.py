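"""Lightweight dimensional-analysis layer.

Every physical routine in this package accepts either plain floats (assumed to
be in the routine's canonical unit, documented in its signature) or
:class:`Quantity` objects carrying explicit units.  Quantities are converted
and dimension-checked at each function boundary, so a wrong unit anywhere in a
units-tagged pipeline raises :class:`DimensionalityError` instead of silently
producing a wrong number.  Magnitudes are stored in coherent SI base units
(m, kg, s, K, mol), which keeps arithmetic exact for SI-coherent inputs.

Only the units this model needs are registered; temperature is absolute
kelvin throughout (no offset units).
"""

from __future__ import annotations

import math
import re
from fractions import Fraction
from numbers import Real

__all__ = [
    "Quantity",
    "UnitError",
    "DimensionalityError",
    "parse_unit",
    "magnitude",
    "has_units",
    "wrap",
]

_NDIM = 5  # base dimensions: m, kg, s, K, mol
_ZERO = (Fraction(0),) * _NDIM
_BASE_NAMES = ("m", "kg", "s", "K", "mol")


class UnitError(ValueError):
    """Raised for unparseable or unknown unit strings."""


class DimensionalityError(ValueError):
    """Raised when an operation mixes incompatible dimensions."""


def _d(m=0, kg=0, s=0, K=0, mol=0):
    return (Fraction(m), Fraction(kg), Fraction(s), Fraction(K), Fraction(mol))


_LENGTH = _d(m=1)
_MASS = _d(kg=1)
_TIME = _d(s=1)
_TEMP = _d(K=1)
_AMOUNT = _d(mol=1)
_PRESSURE = _d(m=-1, kg=1, s=-2)
_ENERGY = _d(m=2, kg=1, s=-2)
_POWER = _d(m=2, kg=1, s=-3)

_REGISTRY: dict[str, tuple[float, tuple]] = {
    "1": (1.0, _ZERO),
    "m": (1.0, _LENGTH),
    "cm": (1e-2, _LENGTH),
    "mm": (1e-3, _LENGTH),
    "km": (1e3, _LENGTH),
    "kg": (1.0, _MASS),
    "g": (1e-3, _MASS),
    "mg": (1e-6, _MASS),
    "s": (1.0, _TIME),
    "min": (60.0, _TIME),
    "h": (3600.0, _TIME),
    "K": (1.0, _TEMP),
    "mol": (1.0, _AMOUNT),
    "mmol": (1e-3, _AMOUNT),
    "umol": (1e-6, _AMOUNT),
    "µmol": (1e-6, _AMOUNT),
    "Pa": (1.0, _PRESSURE),
    "hPa": (1e2, _PRESSURE),
    "kPa": (1e3, _PRESSURE),
    "MPa": (1e6, _PRESSURE),
    "bar": (1e5, _PRESSURE),
    "J": (1.0, _ENERGY),
    "kJ": (1e3, _ENERGY),
    "W": (1.0, _POWER),
    "kW": (1e3, _POWER),
}

_TOKEN = re.compile(r"([*/]?)\s*([A-Za-zµ]+|1)(?:\^(-?\d+))?\s*")
_PARSE_CACHE: dict[str, tuple[float, tuple]] = {}


def parse_unit(spec: str) -> tuple[float, tuple]:
    """Parse a unit string like ``"W/m^2"`` into ``(si_factor, dims)``.

    Grammar: tokens joined by ``*`` or ``/`` with optional integer exponents
    after ``^``; the leading token needs no operator.  ``"1"`` (or ``""``) is
    dimensionless.
    """
    cached = _PARSE_CACHE.get(spec)
    if cached is not None:
        return cached
    text = spec.strip()
    if text in ("", "1"):
        result = (1.0, _ZERO)
        _PARSE_CACHE[spec] = result
        return result
    factor = 1.0
    dims = [Fraction(0)] * _NDIM
    pos = 0
    first = True
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None or m.end() == pos:
            raise UnitError(f"cannot parse unit {spec!r} at position {pos}")
        op, name, exp = m.group(1), m.group(2), m.group(3)
        if first and op:
            raise UnitError(f"unit {spec!r} must not start with {op!r}")
        if not first and not op:
            raise UnitError(f"missing operator in unit {spec!r}")
        entry = _REGISTRY.get(name)
        if entry is None:
            raise UnitError(f"unknown unit {name!r} in {spec!r}")
        e = int(exp) if exp else 1
        if op == "/":
            e = -e
        f, d = entry
        factor *= f ** e
        for i in range(_NDIM):
            dims[i] += Fraction(e) * d[i]
        pos = m.end()
        first = False
    result = (factor, tuple(dims))
    _PARSE_CACHE[spec] = result
    return result


def _dim_str(dims) -> str:
    parts = []
    for name, p in zip(_BASE_NAMES, dims):
        if p != 0:
            parts.append(name if p == 1 else f"{name}^{p}")
    return " ".join(parts) if parts else "1"


class Quantity:
    """A float magnitude with SI dimensions.

    The magnitude is stored in coherent SI base units; ``m_as(unit)`` returns
    the plain number expressed in ``unit`` after a dimension check.
    """

    __slots__ = ("magnitude", "dims")

    def __init__(self, value: float, unit: str = "1"):
        factor, dims = parse_unit(unit)
        object.__setattr__(self, "magnitude", float(value) * factor)
        object.__setattr__(self, "dims", dims)

    @classmethod
    def _from_base(cls, magnitude: float, dims) -> "Quantity":
        q = cls.__new__(cls)
        object.__setattr__(q, "magnitude", float(magnitude))
        object.__setattr__(q, "dims", dims)
        return q

    def __setattr__(self, name, value):  # immutable
        raise AttributeError("Quantity is immutable")

    # -- conversion ------------------------------------------------------
    @property
    def dimensionless(self) -> bool:
        return all(p == 0 for p in self.dims)

    def m_as(self, unit: str) -> float:
        factor, dims = parse_unit(unit)
        if dims != self.dims:
            raise DimensionalityError(
                f"cannot express [{_dim_str(self.dims)}] in {unit!r} "
                f"[{_dim_str(dims)}]"
            )
        return self.magnitude / factor

    def to(self, unit: str) -> "Quantity":
        self.m_as(unit)  # dimension check
        return self

    def __float__(self) -> float:
        if not self.dimensionless:
            raise DimensionalityError(
                f"cannot convert [{_dim_str(self.dims)}] to a bare float"
            )
        return self.magnitude

    # -- arithmetic ------------------------------------------------------
    def _coerce(self, other):
        if isinstance(other, Quantity):
            return other
        if isinstance(other, Real):
            return Quantity._from_base(float(other), _ZERO)
        return None

    def __add__(self, other):
        o = self._coerce(other)
        if o is None:
            return NotImplemented
        if o.dims != self.dims:
            raise DimensionalityError(
                f"cannot add [{_dim_str(self.dims)}] and [{_dim_str(o.dims)}]"
            )
        return Quantity._from_base(self.magnitude + o.magnitude, self.dims)

    __radd__ = __add__

    def __sub__(self, other):
        o = self._coerce(other)
        if o is None:
            return NotImplemented
        if o.dims != self.dims:
            raise DimensionalityError(
                f"cannot subtract [{_dim_str(o.dims)}] from [{_dim_str(self.dims)}]"
            )
        return Quantity._from_base(self.magnitude - o.magnitude, self.dims)

    def __rsub__(self, other):
        o = self._coerce(other)
        if o is None:
            return NotImplemented
        return o.__sub__(self)

    def __mul__(self, other):
        o = self._coerce(other)
        if o is None:
            return NotImplemented
        dims = tuple(a + b for a, b in zip(self.dims, o.dims))
        return Quantity._from_base(self.magnitude * o.magnitude, dims)

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = self._coerce(other)
        if o is None:
            return NotImplemented
        dims = tuple(a - b for a, b in zip(self.dims, o.dims))
        return Quantity._from_base(self.magnitude / o.magnitude, dims)

    def __rtruediv__(self, other):
        o = self._coerce(other)
        if o is None:
            return NotImplemented
        return o.__truediv__(self)

    def __pow__(self, exponent):
        if not isinstance(exponent, Real):
            return NotImplemented
        if self.dimensionless:
            return Quantity._from_base(self.magnitude ** float(exponent), _ZERO)
        if float(exponent) != int(exponent):
            raise DimensionalityError(
                "fractional powers are only defined for dimensionless quantities"
            )
        e = int(exponent)
        dims = tuple(p * e for p in self.dims)
        return Quantity._from_base(self.magnitude ** e, dims)

    def __neg__(self):
        return Quantity._from_base(-self.magnitude, self.dims)

    def __abs__(self):
        return Quantity._from_base(abs(self.magnitude), self.dims)

    # -- comparisons -----------------------------------------------------
    def _cmp_mag(self, other):
        o = self._coerce(other)
        if o is None:
            raise TypeError(f"cannot compare Quantity with {type(other)!r}")
        if o.dims != self.dims:
            raise DimensionalityError(
                f"cannot compare [{_dim_str(self.dims)}] with [{_dim_str(o.dims)}]"
            )
        return o.magnitude

    def __eq__(self, other):
        try:
            return self.magnitude == self._cmp_mag(other)
        except (TypeError, DimensionalityError):
            return NotImplemented

    def __lt__(self, other):
        return self.magnitude < self._cmp_mag(other)

    def __le__(self, other):
        return self.magnitude <= self._cmp_mag(other)

    def __gt__(self, other):
        return self.magnitude > self._cmp_mag(other)

    def __ge__(self, other):
        return self.magnitude >= self._cmp_mag(other)

    def __hash__(self):
        return hash((self.magnitude, self.dims))

    def __repr__(self):
        return f"Quantity({self.magnitude!r}, {_dim_str(self.dims)!r})"


def magnitude(x, unit: str) -> float:
    """Value of ``x`` in ``unit``: converts a Quantity, passes a float through.

    A plain float is taken to be expressed in ``unit`` already — this is the
    unitless fast path.
    """
    if isinstance(x, Quantity):
        return x.m_as(unit)
    return float(x)


def has_units(*xs) -> bool:
    return any(isinstance(x, Quantity) for x in xs)


def wrap(value: float, unit: str, unitful: bool):
    """Tag ``value`` (expressed in ``unit``) as a Quantity iff ``unitful``."""
    if unitful:
        return Quantity(value, unit)
    return value


def exp(x) -> float:
    return math.exp(float(x))


def log(x) -> float:
    return math.log(float(x))


def log10(x) -> float:
    return math.log10(float(x))
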