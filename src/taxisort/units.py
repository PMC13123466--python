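"""Unit-suffixed quantity parsing.

The library works in strict SI internally (kg, m, s, N, Pa s).  Hand-written
configuration files, however, naturally mix g/mL, mm/s, nN and minutes, and
unit-conversion slips are the dominant hazard in this kind of desk model.
Values read from configs may therefore be either plain numbers (taken as SI)
or strings with an explicit unit suffix, e.g. ``"0.5 mm/s"``, ``"1.09 g/mL"``,
``"4.78 mPa*s"``, ``"0.58 nN"``, ``"4.65 s"``, ``"3.3 min"``.
"""

from __future__ import annotations

import re

from .errors import InvalidInputError

# unit -> (factor to SI, dimension tag). Keys are normalised (see _norm).
_UNITS: dict[str, tuple[float, str]] = {
    # length
    "m": (1.0, "length"),
    "cm": (1e-2, "length"),
    "mm": (1e-3, "length"),
    "um": (1e-6, "length"),
    # volume
    "m3": (1.0, "volume"),
    "cm3": (1e-6, "volume"),
    "mm3": (1e-9, "volume"),
    "ml": (1e-6, "volume"),
    "ul": (1e-9, "volume"),
    "l": (1e-3, "volume"),
    # time
    "s": (1.0, "time"),
    "ms": (1e-3, "time"),
    "min": (60.0, "time"),
    "h": (3600.0, "time"),
    # velocity
    "m/s": (1.0, "velocity"),
    "cm/s": (1e-2, "velocity"),
    "mm/s": (1e-3, "velocity"),
    "um/s": (1e-6, "velocity"),
    "mm/min": (1e-3 / 60.0, "velocity"),
    # acceleration
    "m/s2": (1.0, "acceleration"),
    # density
    "kg/m3": (1.0, "density"),
    "g/ml": (1e3, "density"),
    "g/cm3": (1e3, "density"),
    "kg/l": (1e3, "density"),
    "g/l": (1.0, "density"),
    # dynamic viscosity
    "pa*s": (1.0, "viscosity"),
    "mpa*s": (1e-3, "viscosity"),
    "cp": (1e-3, "viscosity"),
    # force
    "n": (1.0, "force"),
    "mn": (1e-3, "force"),
    "un": (1e-6, "force"),
    "nn": (1e-9, "force"),
    "pn": (1e-12, "force"),
    # frequency / rate
    "hz": (1.0, "frequency"),
    "1/s": (1.0, "rate"),
    "s-1": (1.0, "rate"),
    "1/min": (1.0 / 60.0, "rate"),
    "min-1": (1.0 / 60.0, "rate"),
    # diffusivity
    "m2/s": (1.0, "diffusivity"),
    "mm2/s": (1e-6, "diffusivity"),
}

_NUM_RE = re.compile(r"^\s*([-+]?[0-9]*\.?[0-9]+(?:[eE][-+]?[0-9]+)?)\s*(.*)$")

_SUPERSCRIPTS = str.maketrans({"²": "2", "³": "3", "⁻": "-", "¹": "1"})


def _norm(unit: str) -> str:
    u = unit.translate(_SUPERSCRIPTS)
    u = u.replace("·", "*").replace("⋅", "*").replace(" ", "")
    u = u.replace("µ", "u").replace("μ", "u")
    u = u.replace("^", "")
    u = u.replace("sec", "s")
    return u.lower()


def parse_quantity(text: str, dim: str | None = None) -> float:
    """Parse ``"<number> <unit>"`` into an SI float.

    With ``dim`` given, the unit's dimension is checked and a bare number is
    rejected only if the unit is missing *and* ambiguous (bare numbers are
    accepted as SI).
    """
    m = _NUM_RE.match(text)
    if not m:
        raise InvalidInputError(f"cannot parse quantity {text!r}")
    value = float(m.group(1))
    unit = m.group(2).strip()
    if not unit:
        return value
    key = _norm(unit)
    if key not in _UNITS:
        raise InvalidInputError(f"unknown unit {unit!r} in {text!r}")
    factor, d = _UNITS[key]
    if dim is not None and d != dim:
        raise InvalidInputError(
            f"expected a {dim} but {text!r} has dimension {d}"
        )
    return value * factor


def to_si(value, dim: str | None = None) -> float:
    """Coerce a config value (number or unit-suffixed string) to SI."""
    if isinstance(value, bool):
        raise InvalidInputError(f"boolean {value!r} is not a quantity")
    if isinstance(value, (int, float)):
        return float(value)
    if isinstance(value, str):
        return parse_quantity(value, dim=dim)
    raise InvalidInputError(f"cannot interpret {value!r} as a quantity")
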