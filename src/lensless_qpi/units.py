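"""Parsing and formatting of unit-suffixed lengths.

All lengths are stored internally in meters; user-facing strings carry an
explicit suffix (``m``, ``cm``, ``mm``, ``um``, ``nm``).
"""

from __future__ import annotations

import re

__all__ = ["parse_length", "format_length", "LENGTH_UNITS"]

LENGTH_UNITS = {"m": 1.0, "cm": 1e-2, "mm": 1e-3, "um": 1e-6, "nm": 1e-9}

_LENGTH_RE = re.compile(
    r"^\s*([+-]?\d+(?:\.\d*)?(?:[eE][+-]?\d+)?)\s*(m|cm|mm|um|nm)\s*$"
)


def parse_length(text) -> float:
    """Convert a unit-suffixed length string (e.g. ``"4.65um"``) to meters.

    Bare numbers (int/float) are taken to already be in meters.
    """
    if isinstance(text, (int, float)):
        return float(text)
    m = _LENGTH_RE.match(str(text))
    if not m:
        raise ValueError(
            f"cannot parse length {text!r}; expected a number with one of "
            f"the suffixes {sorted(LENGTH_UNITS)}"
        )
    return float(m.group(1)) * LENGTH_UNITS[m.group(2)]


def format_length(meters: float) -> str:
    """Render a length in meters with the most natural suffix."""
    a = abs(meters)
    if a == 0:
        return "0m"
    for unit in ("m", "cm", "mm", "um", "nm"):
        scale = LENGTH_UNITS[unit]
        if a >= scale:
            value = meters / scale
            return f"{value:.12g}{unit}"
    return f"{meters / LENGTH_UNITS['nm']:.12g}nm"
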