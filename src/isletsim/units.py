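"""Unit handling for configuration values.

Internally everything is strict SI: metres, seconds, mol·m⁻³ for
concentrations (numerically identical to mM), Pa·s for viscosity.
Configuration files may attach a unit suffix to any number, written as a
string like ``"150 um"`` or ``"3 mM"``; plain numbers are taken as SI.

Oxygen is special: partial pressures in mmHg are accepted and converted with
a linear Henry coefficient fixed by the stated equivalence
0.200 mol·m⁻³ ↔ 140 mmHg.
"""

from __future__ import annotations

import re

#: Henry coefficient for oxygen in aqueous medium at 37 °C [mol·m⁻³ per mmHg],
#: fixed by the pair 0.200 mol·m⁻³ ≈ 140 mmHg.
OXYGEN_HENRY = 0.200 / 140.0

# unit -> (dimension, factor to SI)
_UNITS = {
    # length
    "m": ("length", 1.0),
    "mm": ("length", 1e-3),
    "um": ("length", 1e-6),
    "µm": ("length", 1e-6),
    "nm": ("length", 1e-9),
    # time
    "s": ("time", 1.0),
    "min": ("time", 60.0),
    "h": ("time", 3600.0),
    # concentration (mol/m^3 == mM)
    "mol/m3": ("concentration", 1.0),
    "mM": ("concentration", 1.0),
    "uM": ("concentration", 1e-3),
    "µM": ("concentration", 1e-3),
    "M": ("concentration", 1e3),
    "mmHg": ("concentration", OXYGEN_HENRY),  # oxygen tension via Henry's law
    # rates
    "mol/m3/s": ("rate", 1.0),
    "mM/s": ("rate", 1.0),
    "uM/s": ("rate", 1e-3),
    "1/s": ("inverse_time", 1.0),
    "/s": ("inverse_time", 1.0),
    "1/min": ("inverse_time", 1.0 / 60.0),
    # speed
    "m/s": ("speed", 1.0),
    "mm/s": ("speed", 1e-3),
    "um/s": ("speed", 1e-6),
    # volumetric flow
    "m3/s": ("flow", 1.0),
    "uL/min": ("flow", 1e-9 / 60.0),
    "mL/min": ("flow", 1e-6 / 60.0),
    "uL/s": ("flow", 1e-9),
    # dynamic viscosity
    "Pa*s": ("viscosity", 1.0),
    "Pa.s": ("viscosity", 1.0),
    "mPa*s": ("viscosity", 1e-3),
    "cP": ("viscosity", 1e-3),
    # density
    "kg/m3": ("density", 1.0),
    "g/mL": ("density", 1e3),
    # diffusivity
    "m2/s": ("diffusivity", 1.0),
    "cm2/s": ("diffusivity", 1e-4),
    # volume
    "m3": ("volume", 1.0),
    "um3": ("volume", 1e-18),
    "uL": ("volume", 1e-9),
}

_QUANTITY_RE = re.compile(r"^\s*([+-]?[\d.eE+-]+)\s*([^\s]+)?\s*$")


class UnitError(ValueError):
    """Raised for unknown units or dimension mismatches."""


def parse_quantity(value, dimension: str) -> float:
    """Convert a config value to SI.

    ``value`` may be a plain number (taken as SI) or a string
    ``"<number> <unit>"``. ``dimension`` names the expected physical
    dimension and is checked against the unit's dimension.
    """
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    if not isinstance(value, str):
        raise UnitError(f"cannot interpret {value!r} as a physical quantity")
    m = _QUANTITY_RE.match(value)
    if not m:
        raise UnitError(f"malformed quantity {value!r}")
    num, unit = m.groups()
    try:
        x = float(num)
    except ValueError as exc:
        raise UnitError(f"malformed number in {value!r}") from exc
    if unit is None:
        return x
    if unit not in _UNITS:
        raise UnitError(f"unknown unit {unit!r} in {value!r}")
    dim, factor = _UNITS[unit]
    if dim != dimension:
        raise UnitError(
            f"unit {unit!r} has dimension {dim!r}, expected {dimension!r}"
        )
    return x * factor
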