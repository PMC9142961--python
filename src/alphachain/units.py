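"""Unit helpers.

Internal convention throughout the package: time in minutes, activity in
kBq, count rates in counts/min.  Everything else is converted at the
boundary.
"""

from __future__ import annotations

LN2 = 0.6931471805599453

#: minutes per unit of time, keyed by unit label
_TIME_UNITS = {
    "ms": 1.0 / 60_000.0,
    "s": 1.0 / 60.0,
    "min": 1.0,
    "h": 60.0,
    "day": 1440.0,
    "d": 1440.0,
}

#: decays per minute in one kBq
DECAYS_PER_MIN_PER_KBQ = 60_000.0


def to_minutes(value: float, unit: str) -> float:
    """Convert a duration given in *unit* (ms/s/min/h/day) to minutes."""
    try:
        factor = _TIME_UNITS[unit]
    except KeyError:
        raise ValueError(
            f"unknown time unit {unit!r}; expected one of {sorted(_TIME_UNITS)}"
        ) from None
    return value * factor


def hours(value: float) -> float:
    """Hours to minutes."""
    return value * 60.0


def days(value: float) -> float:
    """Days to minutes."""
    return value * 1440.0
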