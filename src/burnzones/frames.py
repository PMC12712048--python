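"""Planar equal-area working frame and geographic conversions.

All geometry processing (buffering, areas, distances) happens in a local
planar frame measured in metres, analogous to an Albers-style equal-area
projection. Longitude/latitude only appear at I/O boundaries (source CSVs
and the final GeoJSON), where a local sinusoidal mapping anchored at the
frame origin converts between the two. Over regional extents (a few hundred
kilometres) the sinusoidal mapping is equal-area and the distortion of
distances is far below the tolerances used anywhere in the pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

# Authalic Earth radius in metres.
EARTH_RADIUS_M = 6_371_007.2

ACRE_M2 = 4046.8564224
ACRE_KM2 = ACRE_M2 / 1e6
MILE_KM = 1.609344


@dataclass(frozen=True)
class LocalFrame:
    """Local planar frame: (0, 0) in metres maps to (lon0, lat0)."""

    lon0: float = -120.0
    lat0: float = 39.0

    def to_lonlat(self, x: float, y: float) -> tuple[float, float]:
        lat = self.lat0 + math.degrees(y / EARTH_RADIUS_M)
        lon = self.lon0 + math.degrees(
            x / (EARTH_RADIUS_M * math.cos(math.radians(lat)))
        )
        return lon, lat

    def to_xy(self, lon: float, lat: float) -> tuple[float, float]:
        y = math.radians(lat - self.lat0) * EARTH_RADIUS_M
        x = (
            math.radians(lon - self.lon0)
            * EARTH_RADIUS_M
            * math.cos(math.radians(lat))
        )
        return x, y


def acres_to_m2(acres: float) -> float:
    return acres * ACRE_M2


def acres_to_km2(acres: float) -> float:
    return acres * ACRE_KM2


def m2_to_acres(m2: float) -> float:
    return m2 / ACRE_M2
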