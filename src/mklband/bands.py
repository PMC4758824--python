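"""Canonical frequency bands used to summarise the time-frequency decomposition.

The six bands span the classical EEG rhythms up to high-gamma; the
high-gamma band deliberately stops at 110 Hz so that a 120 Hz line-noise
harmonic cannot leak into it.
"""
from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [lo_hz, hi_hz)."""

    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self) -> None:
        if not self.lo_hz < self.hi_hz:
            raise ValueError(f"band {self.name}: lo {self.lo_hz} must be < hi {self.hi_hz}")


#: Canonical bands: delta 1-4, theta 4-8, alpha 8-12, beta 15-25,
#: low-gamma 30-55 and high-gamma 70-110 Hz.
CANONICAL_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 15.0, 25.0),
    BandDefinition("low_gamma", 30.0, 55.0),
    BandDefinition("high_gamma", 70.0, 110.0),
)

BAND_NAMES: tuple[str, ...] = tuple(b.name for b in CANONICAL_BANDS)

_ALIASES = {
    "δ": "delta", "θ": "theta", "α": "alpha", "β": "beta",
    "low-γ": "low_gamma", "high-γ": "high_gamma",
    "low-gamma": "low_gamma", "high-gamma": "high_gamma",
    "hfb": "high_gamma",
}


def get_band(name: str) -> BandDefinition:
    """Look up a canonical band by name (Greek-letter aliases accepted)."""
    key = _ALIASES.get(name, _ALIASES.get(name.lower(), name.lower()))
    for b in CANONICAL_BANDS:
        if b.name == key:
            return b
    raise ValueError(f"unknown band {name!r}; expected one of {BAND_NAMES}")
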