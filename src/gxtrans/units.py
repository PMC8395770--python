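"""Treadmill speed unit conversions.

The canonical internal unit is metres per minute, the unit in which the
conventional treadmill metabolic equations are stated.  Conversion factors:
1 mph = 26.8224 m/min, 1 m/s = 60 m/min, 1 km/h = 1000/60 m/min.
"""

M_PER_MIN = "m/min"

_ALIASES = {
    "m/min": "m/min",
    "m_min": "m/min",
    "mmin": "m/min",
    "m/s": "m/s",
    "m_s": "m/s",
    "ms": "m/s",
    "mph": "mph",
    "km/h": "km/h",
    "km_h": "km/h",
    "kmh": "km/h",
}

_TO_M_MIN = {
    "m/min": 1.0,
    "m/s": 60.0,
    "mph": 26.8224,
    "km/h": 1000.0 / 60.0,
}


def canonical_unit(unit: str) -> str:
    """Normalise a unit spelling (``m_s``, ``kmh`` ...) to its canonical form."""
    try:
        return _ALIASES[unit.strip().lower()]
    except KeyError:
        raise ValueError(
            f"unknown speed unit {unit!r}; expected one of {sorted(_TO_M_MIN)}"
        ) from None


def to_m_per_min(value: float, unit: str = M_PER_MIN) -> float:
    """Convert a speed in ``unit`` to m/min."""
    return value * _TO_M_MIN[canonical_unit(unit)]


def from_m_per_min(value: float, unit: str = M_PER_MIN) -> float:
    """Convert a speed in m/min to ``unit``."""
    return value / _TO_M_MIN[canonical_unit(unit)]
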