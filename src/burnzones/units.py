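"""Unit conversions behind the community / WUI thresholds.

The published thresholds are quoted in customary units (persons per square
mile, houses per 40 acres) and used in metric form. These helpers perform
the conversions exactly and expose the truncation conventions the metric
figures follow.
"""

from __future__ import annotations

import math

from .frames import ACRE_M2, MILE_KM


def truncate(value: float, ndigits: int = 0) -> float:
    """Truncate (round toward zero) to ``ndigits`` decimal places."""
    factor = 10.0**ndigits
    return math.trunc(value * factor) / factor


def persons_per_mile2_to_km2(value: float) -> float:
    """Convert a density in persons/mi^2 to persons/km^2."""
    return value / (MILE_KM**2)


def density_threshold_km2(persons_per_mile2: float = 250.0) -> int:
    """Interface-community density floor in persons/km^2, truncated."""
    return int(truncate(persons_per_mile2_to_km2(persons_per_mile2)))


def houses_per_km2(houses: float, acres: float) -> float:
    """Convert a housing density of ``houses`` per ``acres`` to houses/km^2."""
    return houses / (acres * ACRE_M2) * 1e6


def housing_threshold_km2(houses: float = 1.0, acres: float = 40.0) -> float:
    """Intermix housing-density floor in houses/km^2, truncated to 2 dp."""
    return truncate(houses_per_km2(houses, acres), 2)
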