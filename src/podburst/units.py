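"""Unit tags and exact conversions to/from SI base units.

All internal computation in :mod:`podburst` is done in SI base units
(m, N, Pa, kg, s, J).  Configuration files and reports use the natural
units of the problem (micrometres, millimetres, megapascals,
millinewtons, milligrams, milliseconds, millijoules), which span nine
orders of magnitude; converting once at the boundary avoids
magnitude-mixing bugs.
"""

from __future__ import annotations

# factor such that  value_SI = value * FACTOR[tag]
_TO_SI: dict[str, float] = {
    "um": 1e-6,
    "mm": 1e-3,
    "m": 1.0,
    "mN": 1e-3,
    "N": 1.0,
    "MPa": 1e6,
    "Pa": 1.0,
    "mg": 1e-6,
    "kg": 1.0,
    "ms": 1e-3,
    "s": 1.0,
    "mJ": 1e-3,
    "J": 1.0,
}

# unicode aliases accepted on input
_ALIASES = {"μm": "um", "µm": "um"}


def _canon(tag: str) -> str:
    tag = _ALIASES.get(tag, tag)
    if tag not in _TO_SI:
        raise ValueError(f"unknown unit tag {tag!r}; known tags: {sorted(_TO_SI)}")
    return tag


def to_si(value: float, tag: str) -> float:
    """Convert ``value`` carrying unit ``tag`` to SI base units."""
    return value * _TO_SI[_canon(tag)]


def from_si(value: float, tag: str) -> float:
    """Convert an SI value to the unit ``tag``. Inverse of :func:`to_si`."""
    return value / _TO_SI[_canon(tag)]
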