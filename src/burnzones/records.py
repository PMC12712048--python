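"""Shared record types passed between pipeline stages.

``SourceEventRecord`` is one cleaned row from one incident source flavor;
``CanonicalFire`` is a resolved incident/complex after linkage;
``PerimeterRecord`` is one burn perimeter from one spatial flavor.
The remaining types are stage outputs documented on their modules.

Every synthetic record carries a hidden ``truth_id`` so tests can score
recovery against the generator; pipeline logic never reads it.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Optional

import pandas as pd
from shapely.geometry.base import BaseGeometry

UNRESOLVED = "__UNRESOLVED__"

SOURCES = ("ics209", "redbooks", "fmag")
PERIMETER_FLAVORS = ("mtbs", "fired", "nifc")

# Source order used for deterministic tie-breaking during resolution.
SOURCE_ORDER = {"redbooks": 0, "ics209": 1, "fmag": 2}


@dataclass
class SourceEventRecord:
    source: str
    source_id: str
    raw_name: str
    clean_name: str
    counties: tuple[tuple[str, str], ...] = ()  # (state, county) pairs
    ignition_date: Optional[dt.date] = None
    containment_date: Optional[dt.date] = None
    year: Optional[int] = None
    civilian_fatalities: Optional[int] = None
    total_fatalities: Optional[int] = None
    destroyed_structures: Optional[int] = None
    damaged_structures: Optional[int] = None
    combined_damaged_destroyed: Optional[int] = None
    origin: Optional[tuple[float, float]] = None  # planar (x, y) metres
    area_acres: Optional[float] = None
    shared_id: Optional[str] = None
    fmag_declaration_date: Optional[dt.date] = None
    threatened_structures: Optional[int] = None
    injuries: Optional[int] = None
    evacuated: Optional[int] = None
    estimated_cost: Optional[float] = None
    truth_id: Optional[str] = None

    @property
    def states(self) -> tuple[str, ...]:
        return tuple(sorted({s for s, _ in self.counties}))

    @property
    def key(self) -> tuple[str, str]:
        return (self.source, self.source_id)

    def match_date(self) -> Optional[dt.date]:
        """Date used for temporal matching; FMAG rows may only carry a
        declaration date."""
        return self.ignition_date or self.fmag_declaration_date


@dataclass
class MatchEvidence:
    name_distance: float
    date_gap_days: Optional[int]
    shared_counties: tuple[tuple[str, str], ...]
    date_waived: bool = False


@dataclass
class EventCluster:
    members: tuple[tuple[str, str], ...]  # sorted (source, source_id) keys
    edges: tuple[tuple[tuple[str, str], tuple[str, str], MatchEvidence], ...]


@dataclass
class CanonicalFire:
    fire_id: str
    names: tuple[str, ...]
    counties: tuple[tuple[str, str], ...]
    ignition_date: Optional[dt.date] = None
    containment_date: Optional[dt.date] = None
    year: Optional[int] = None
    civilian_fatalities: Optional[int] = None
    total_fatalities: Optional[int] = None
    destroyed_structures: Optional[int] = None
    damaged_structures: Optional[int] = None
    combined_damaged_destroyed: Optional[int] = None
    fmag: bool = False
    fmag_declaration_date: Optional[dt.date] = None
    origin: Optional[tuple[float, float]] = None
    area_acres: Optional[float] = None
    shared_ids: tuple[str, ...] = ()
    threatened_structures: Optional[int] = None
    injuries: Optional[int] = None
    evacuated: Optional[int] = None
    estimated_cost: Optional[float] = None
    members: tuple[tuple[str, str], ...] = ()

    @property
    def states(self) -> tuple[str, ...]:
        return tuple(sorted({s for s, _ in self.counties}))

    @property
    def ignition_year(self) -> Optional[int]:
        if self.ignition_date is not None:
            return self.ignition_date.year
        return self.year


@dataclass
class CriteriaFlags:
    fatality_met: bool = False
    structure_met: bool = False
    fmag_met: bool = False
    fatality_rule: str = "none"
    structure_rule: str = "none"
    fmag_rule: str = "none"

    @property
    def any_met(self) -> bool:
        return self.fatality_met or self.structure_met or self.fmag_met


@dataclass
class PerimeterRecord:
    flavor: str
    perimeter_id: str
    geometry: BaseGeometry
    area_acres: float
    name: Optional[str] = None
    shared_id: Optional[str] = None
    ignition_date: Optional[dt.date] = None
    containment_date: Optional[dt.date] = None
    year: Optional[int] = None
    truth_id: Optional[str] = None


@dataclass
class GeometryAssignment:
    geometry: Optional[BaseGeometry]  # polygon, point, or None
    geometry_source: str  # mtbs|fired|nifc|circular_buffer|point_only|county_only
    link_method: str  # tier label
    area_km2: Optional[float] = None
    perimeter_key: Optional[tuple[str, str]] = None  # (flavor, perimeter_id)


@dataclass
class ExposureResult:
    max_density: float = float("nan")
    mean_density: float = float("nan")
    density_flag: Optional[bool] = None
    wui_class: str = "none"  # intermix|interface|both|none
    community_flag: Optional[bool] = None
    epoch_year: Optional[int] = None
    out_of_extent: bool = False


@dataclass
class DisasterRecord:
    fire_id: str
    names: tuple[str, ...]
    counties: tuple[tuple[str, str], ...]
    ignition_date: Optional[dt.date]
    containment_date: Optional[dt.date]
    year: Optional[int]
    civilian_fatalities: Optional[int]
    total_fatalities: Optional[int]
    destroyed_structures: Optional[int]
    damaged_structures: Optional[int]
    combined_damaged_destroyed: Optional[int]
    fmag: bool
    fmag_declaration_date: Optional[dt.date]
    origin: Optional[tuple[float, float]]
    area_acres: Optional[float]
    area_km2: Optional[float]
    threatened_structures: Optional[int]
    injuries: Optional[int]
    evacuated: Optional[int]
    estimated_cost: Optional[float]
    fatality_met: bool
    structure_met: bool
    fmag_met: bool
    fatality_rule: str
    structure_rule: str
    fmag_rule: str
    max_density: float
    mean_density: float
    density_flag: Optional[bool]
    wui_class: str
    community_flag: Optional[bool]
    geometry: Optional[BaseGeometry]
    geometry_source: str
    link_method: str

    @property
    def states(self) -> tuple[str, ...]:
        return tuple(sorted({s for s, _ in self.counties}))

    @property
    def ignition_year(self) -> Optional[int]:
        if self.ignition_date is not None:
            return self.ignition_date.year
        return self.year

    @property
    def is_disaster(self) -> bool:
        """Full definition: any harm criterion AND community proximity."""
        return bool(
            (self.fatality_met or self.structure_met or self.fmag_met)
            and self.community_flag
        )


# ---------------------------------------------------------------------------
# (de)serialization helpers for the unified cleaned-event CSV schema
# ---------------------------------------------------------------------------

_COUNTY_SEP = "|"
_COUNTY_PAIR_SEP = ":"


def counties_to_str(counties: tuple[tuple[str, str], ...]) -> str:
    return _COUNTY_SEP.join(f"{s}{_COUNTY_PAIR_SEP}{c}" for s, c in counties)


def counties_from_str(text: str) -> tuple[tuple[str, str], ...]:
    if not text or pd.isna(text):
        return ()
    pairs = []
    for chunk in str(text).split(_COUNTY_SEP):
        state, _, county = chunk.partition(_COUNTY_PAIR_SEP)
        pairs.append((state, county))
    return tuple(pairs)


def _date_str(d: Optional[dt.date]) -> Optional[str]:
    return None if d is None else d.isoformat()


def _date_from(v) -> Optional[dt.date]:
    if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
        return None
    if isinstance(v, dt.date):
        return v
    return dt.date.fromisoformat(str(v))


def _opt_int(v) -> Optional[int]:
    if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
        return None
    return int(v)


def _opt_float(v) -> Optional[float]:
    if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
        return None
    return float(v)


def events_to_frame(records: list[SourceEventRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "source": r.source,
                "source_id": r.source_id,
                "raw_name": r.raw_name,
                "clean_name": r.clean_name,
                "counties": counties_to_str(r.counties),
                "ignition_date": _date_str(r.ignition_date),
                "containment_date": _date_str(r.containment_date),
                "year": r.year,
                "civilian_fatalities": r.civilian_fatalities,
                "total_fatalities": r.total_fatalities,
                "destroyed_structures": r.destroyed_structures,
                "damaged_structures": r.damaged_structures,
                "combined_damaged_destroyed": r.combined_damaged_destroyed,
                "origin_x": None if r.origin is None else r.origin[0],
                "origin_y": None if r.origin is None else r.origin[1],
                "area_acres": r.area_acres,
                "shared_id": r.shared_id,
                "fmag_declaration_date": _date_str(r.fmag_declaration_date),
                "threatened_structures": r.threatened_structures,
                "injuries": r.injuries,
                "evacuated": r.evacuated,
                "estimated_cost": r.estimated_cost,
                "truth_id": r.truth_id,
            }
        )
    return pd.DataFrame(rows)


def events_from_frame(frame: pd.DataFrame) -> list[SourceEventRecord]:
    records = []
    for row in frame.to_dict("records"):
        origin = None
        if _opt_float(row.get("origin_x")) is not None:
            origin = (float(row["origin_x"]), float(row["origin_y"]))
        records.append(
            SourceEventRecord(
                source=row["source"],
                source_id=str(row["source_id"]),
                raw_name=str(row["raw_name"]),
                clean_name=str(row["clean_name"]),
                counties=counties_from_str(row.get("counties", "")),
                ignition_date=_date_from(row.get("ignition_date")),
                containment_date=_date_from(row.get("containment_date")),
                year=_opt_int(row.get("year")),
                civilian_fatalities=_opt_int(row.get("civilian_fatalities")),
                total_fatalities=_opt_int(row.get("total_fatalities")),
                destroyed_structures=_opt_int(row.get("destroyed_structures")),
                damaged_structures=_opt_int(row.get("damaged_structures")),
                combined_damaged_destroyed=_opt_int(
                    row.get("combined_damaged_destroyed")
                ),
                origin=origin,
                area_acres=_opt_float(row.get("area_acres")),
                shared_id=(
                    None
                    if row.get("shared_id") is None
                    or (isinstance(row.get("shared_id"), float) and pd.isna(row["shared_id"]))
                    else str(row["shared_id"])
                ),
                fmag_declaration_date=_date_from(row.get("fmag_declaration_date")),
                threatened_structures=_opt_int(row.get("threatened_structures")),
                injuries=_opt_int(row.get("injuries")),
                evacuated=_opt_int(row.get("evacuated")),
                estimated_cost=_opt_float(row.get("estimated_cost")),
                truth_id=(
                    None
                    if row.get("truth_id") is None
                    or (isinstance(row.get("truth_id"), float) and pd.isna(row["truth_id"]))
                    else str(row["truth_id"])
                ),
            )
        )
    return records
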