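"""Minimal unit-aware parsing for configuration values.

Process parameters arrive in config files and CLI flags as strings such as
``"1 mL/min"`` or ``"27 mPa.s"``.  Every quantity must carry an explicit
unit; bare numbers are rejected so that convention errors (rpm vs rad/s,
mL vs m^3) cannot slip in silently.  The parser reduces each quantity to
SI and checks it against the dimension the caller expects.  The library
API itself works on plain SI floats.
"""

from __future__ import annotations

import re

# unit alias -> (dimension, factor to SI)
_UNITS: dict[str, tuple[str, float]] = {
    # length
    "m": ("length", 1.0),
    "cm": ("length", 1e-2),
    "mm": ("length", 1e-3),
    "um": ("length", 1e-6),
    "µm": ("length", 1e-6),
    "μm": ("length", 1e-6),
    "nm": ("length", 1e-9),
    # area
    "m^2": ("area", 1.0),
    "mm^2": ("area", 1e-6),
    # volume
    "m^3": ("volume", 1.0),
    "L": ("volume", 1e-3),
    "mL": ("volume", 1e-6),
    "uL": ("volume", 1e-9),
    "µL": ("volume", 1e-9),
    "μL": ("volume", 1e-9),
    # time
    "s": ("time", 1.0),
    "ms": ("time", 1e-3),
    "min": ("time", 60.0),
    "h": ("time", 3600.0),
    # speed
    "m/s": ("speed", 1.0),
    "mm/s": ("speed", 1e-3),
    # volumetric flow
    "m^3/s": ("flow", 1.0),
    "mL/min": ("flow", 1e-6 / 60.0),
    "mL/h": ("flow", 1e-6 / 3600.0),
    "uL/min": ("flow", 1e-9 / 60.0),
    "µL/min": ("flow", 1e-9 / 60.0),
    "L/min": ("flow", 1e-3 / 60.0),
    # density
    "kg/m^3": ("density", 1.0),
    "g/mL": ("density", 1e3),
    "g/cm^3": ("density", 1e3),
    "g/L": ("density", 1.0),
    # dynamic viscosity
    "Pa.s": ("viscosity", 1.0),
    "mPa.s": ("viscosity", 1e-3),
    "cP": ("viscosity", 1e-3),
    # diffusivity
    "m^2/s": ("diffusivity", 1.0),
    "cm^2/s": ("diffusivity", 1e-4),
    # rotational speed (SI: rad/s)
    "rad/s": ("rotational_speed", 1.0),
    "rev/s": ("rotational_speed", 2.0 * 3.141592653589793),
    "rpm": ("rotational_speed", 2.0 * 3.141592653589793 / 60.0),
    "rev/min": ("rotational_speed", 2.0 * 3.141592653589793 / 60.0),
    # rate
    "1/s": ("rate", 1.0),
    "s^-1": ("rate", 1.0),
    # power
    "W": ("power", 1.0),
    "mW": ("power", 1e-3),
    # mass concentration
    "%w/v": ("mass_concentration", 10.0),  # g per 100 mL -> kg/m^3
    "g/100mL": ("mass_concentration", 10.0),
    "mg/mL": ("mass_concentration", 1.0),
    # dimensionless
    "-": ("dimensionless", 1.0),
    "%": ("dimensionless", 0.01),
}

_QTY_RE = re.compile(r"^\s*([+-]?\d+(?:\.\d*)?(?:[eE][+-]?\d+)?)\s*(\S.*?)\s*$")


class UnitError(ValueError):
    """A quantity string is missing a unit, or the unit does not match."""


def parse_quantity(text: str | float, expect: str | None = None) -> float:
    """Parse ``"<number> <unit>"`` and return the value in SI units.

    Parameters
    ----------
    text:
        Quantity string, e.g. ``"1 mL/min"``.  Bare numbers are rejected.
    expect:
        Required dimension name (``"length"``, ``"flow"``, ...).  ``None``
        accepts any known unit.
    """
    if isinstance(text, (int, float)):
        raise UnitError(
            f"bare number {text!r}: quantities must carry an explicit unit "
            f"(e.g. '1 mL/min')"
        )
    m = _QTY_RE.match(text)
    if m is None:
        raise UnitError(f"cannot parse quantity {text!r}")
    value, unit = float(m.group(1)), m.group(2)
    unit = unit.replace("·", ".").replace("**", "^").replace(" ", "")
    if unit not in _UNITS:
        raise UnitError(f"unknown unit {unit!r} in {text!r}")
    dim, factor = _UNITS[unit]
    if expect is not None and dim != expect:
        raise UnitError(f"{text!r} has dimension {dim!r}, expected {expect!r}")
    return value * factor
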