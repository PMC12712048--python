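"""Attach burn-zone geometry to preliminary fires via tiered matching.

Tiers, tried in order with the first success recorded as ``link_method``:

1. ``shared_id``   — interagency ID equality against the perimeter sets.
2. ``mtbs_name``   — large-fire flavor by name + location + ignition ±30 d.
3. ``fired_origin``— nameless flavor by point-of-origin containment + date.
4. ``nifc_name``   — year-only flavor by name + location + ignition year ±30 d.
5. ``circular_buffer`` — circle from reported origin and burn area.
6. ``point_only``  — origin but no area.
7. ``county_only`` — no feasible origin; record kept without geometry.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
from shapely.geometry import MultiPolygon, Point, Polygon
from shapely.geometry.base import BaseGeometry

from .criteria import CriteriaConfig, evaluate_criteria
from .frames import acres_to_m2
from .linkage import jw_distance
from .records import (
    CanonicalFire,
    CriteriaFlags,
    GeometryAssignment,
    PerimeterRecord,
    UNRESOLVED,
)
from .standardize import Gazetteer

TIER_ORDER = (
    "shared_id",
    "mtbs_name",
    "fired_origin",
    "nifc_name",
    "circular_buffer",
    "point_only",
    "county_only",
)
TIER_RANK = {name: i for i, name in enumerate(TIER_ORDER)}


@dataclass
class GeoLinkConfig:
    jw_max: float = 0.25
    prefix_factor: float = 0.1
    date_window_days: int = 30
    county_distance_m: float = 10_000.0
    origin_distance_m: float = 10_000.0
    fired_origin_distance_m: float = 1_000.0
    circle_quad_segs: int = 64  # 4 * quad_segs = 256 segments


def repair_geometry(geom: BaseGeometry) -> MultiPolygon:
    """Zero-width-buffer repair, then cast to multipolygon."""
    if not geom.is_valid:
        geom = geom.buffer(0)
    if isinstance(geom, Polygon):
        return MultiPolygon([geom])
    if isinstance(geom, MultiPolygon):
        return geom
    raise ValueError(f"cannot repair geometry of type {geom.geom_type}")


def circle_from_point(
    origin: tuple[float, float],
    area_acres: Optional[float],
    quad_segs: int = 64,
) -> BaseGeometry:
    """Circular burn-zone approximation centred on the reported origin.

    The circle's planar area equals the reported burn area to within 1%
    (256-segment approximation). With no reported area, the point itself is
    returned unchanged.
    """
    point = Point(origin)
    if area_acres is None:
        return point
    if not math.isfinite(area_acres) or area_acres <= 0:
        raise ValueError(f"invalid burn area {area_acres!r}")
    area_m2 = acres_to_m2(area_acres)
    radius = math.sqrt(area_m2 / math.pi)
    return point.buffer(radius, quad_segs=quad_segs)


def _names_match(
    fire: CanonicalFire, perimeter: PerimeterRecord, cfg: GeoLinkConfig
) -> Optional[float]:
    if perimeter.name is None:
        return None
    dist = min(
        jw_distance(name, perimeter.name, cfg.prefix_factor)
        for name in fire.names
    )
    return dist if dist <= cfg.jw_max else None


def _location_match(
    fire: CanonicalFire,
    perimeter: PerimeterRecord,
    gazetteer: Optional[Gazetteer],
    cfg: GeoLinkConfig,
) -> bool:
    """County-within-10-km rule, plus an origin distance cap when both
    sides carry coordinates."""
    if fire.origin is not None:
        if perimeter.geometry.distance(Point(fire.origin)) > cfg.origin_distance_m:
            return False
    county_geoms = []
    if gazetteer is not None:
        for state, county in fire.counties:
            if county == UNRESOLVED or state not in gazetteer.counties:
                continue
            geom = gazetteer.geometry(state, county)
            if geom is not None:
                county_geoms.append(geom)
    if county_geoms:
        return any(
            perimeter.geometry.distance(g) <= cfg.county_distance_m
            for g in county_geoms
        )
    # No county geometry available: fall back on the origin test alone.
    return fire.origin is not None


def _date_within(
    fire_date: Optional[dt.date],
    perimeter_date: Optional[dt.date],
    window_days: int,
) -> bool:
    if fire_date is None or perimeter_date is None:
        return False
    return abs((fire_date - perimeter_date).days) <= window_days


def _year_window_match(
    fire_date: Optional[dt.date], year: Optional[int], window_days: int
) -> bool:
    if fire_date is None or year is None:
        return False
    start = dt.date(year, 1, 1) - dt.timedelta(days=window_days)
    end = dt.date(year, 12, 31) + dt.timedelta(days=window_days)
    return start <= fire_date <= end


def _tier_shared_id(
    fire: CanonicalFire, perimeters: dict[str, Sequence[PerimeterRecord]]
) -> Optional[PerimeterRecord]:
    if not fire.shared_ids:
        return None
    ids = set(fire.shared_ids)
    for flavor in ("mtbs", "fired", "nifc"):
        for perim in perimeters.get(flavor, ()):
            if perim.shared_id is not None and perim.shared_id in ids:
                return perim
    return None


def _tier_mtbs_name(
    fire: CanonicalFire,
    perimeters: dict[str, Sequence[PerimeterRecord]],
    gazetteer: Optional[Gazetteer],
    cfg: GeoLinkConfig,
) -> Optional[PerimeterRecord]:
    candidates = []
    for perim in perimeters.get("mtbs", ()):
        dist = _names_match(fire, perim, cfg)
        if dist is None:
            continue
        if not _date_within(
            fire.ignition_date, perim.ignition_date, cfg.date_window_days
        ):
            continue
        if not _location_match(fire, perim, gazetteer, cfg):
            continue
        candidates.append((dist, perim.perimeter_id, perim))
    return min(candidates)[2] if candidates else None


def _tier_fired_origin(
    fire: CanonicalFire,
    perimeters: dict[str, Sequence[PerimeterRecord]],
    cfg: GeoLinkConfig,
) -> Optional[PerimeterRecord]:
    if fire.origin is None:
        return None
    origin = Point(fire.origin)
    candidates = []
    for perim in perimeters.get("fired", ()):
        if not _date_within(
            fire.ignition_date, perim.ignition_date, cfg.date_window_days
        ):
            continue
        distance = perim.geometry.distance(origin)
        if distance <= cfg.fired_origin_distance_m:
            candidates.append((distance, perim.perimeter_id, perim))
    return min(candidates)[2] if candidates else None


def _tier_nifc_name(
    fire: CanonicalFire,
    perimeters: dict[str, Sequence[PerimeterRecord]],
    gazetteer: Optional[Gazetteer],
    cfg: GeoLinkConfig,
) -> Optional[PerimeterRecord]:
    candidates = []
    for perim in perimeters.get("nifc", ()):
        dist = _names_match(fire, perim, cfg)
        if dist is None:
            continue
        if not _year_window_match(
            fire.ignition_date, perim.year, cfg.date_window_days
        ):
            continue
        if not _location_match(fire, perim, gazetteer, cfg):
            continue
        candidates.append((dist, perim.perimeter_id, perim))
    return min(candidates)[2] if candidates else None


def assign_geometry(
    fire: CanonicalFire,
    perimeters: dict[str, Sequence[PerimeterRecord]],
    gazetteer: Optional[Gazetteer] = None,
    cfg: Optional[GeoLinkConfig] = None,
) -> GeometryAssignment:
    """Attach the best available burn-zone geometry to one fire."""
    cfg = cfg or GeoLinkConfig()

    perim = _tier_shared_id(fire, perimeters)
    if perim is not None:
        return _from_perimeter(perim, "shared_id")
    perim = _tier_mtbs_name(fire, perimeters, gazetteer, cfg)
    if perim is not None:
        return _from_perimeter(perim, "mtbs_name")
    perim = _tier_fired_origin(fire, perimeters, cfg)
    if perim is not None:
        return _from_perimeter(perim, "fired_origin")
    perim = _tier_nifc_name(fire, perimeters, gazetteer, cfg)
    if perim is not None:
        return _from_perimeter(perim, "nifc_name")

    if fire.origin is not None:
        geom = circle_from_point(fire.origin, fire.area_acres, cfg.circle_quad_segs)
        if isinstance(geom, Point):
            return GeometryAssignment(
                geometry=geom,
                geometry_source="point_only",
                link_method="point_only",
                area_km2=None,
            )
        return GeometryAssignment(
            geometry=geom,
            geometry_source="circular_buffer",
            link_method="circular_buffer",
            area_km2=geom.area / 1e6,
        )

    if any(c != UNRESOLVED for _, c in fire.counties) or fire.counties:
        return GeometryAssignment(
            geometry=None,
            geometry_source="county_only",
            link_method="county_only",
            area_km2=None,
        )
    raise ValueError(
        f"fire {fire.fire_id} has neither origin nor county; rejected"
    )


def _from_perimeter(perim: PerimeterRecord, tier: str) -> GeometryAssignment:
    geom = repair_geometry(perim.geometry)
    return GeometryAssignment(
        geometry=geom,
        geometry_source=perim.flavor,
        link_method=tier,
        area_km2=geom.area / 1e6,
        perimeter_key=(perim.flavor, perim.perimeter_id),
    )


def merge_linked_groups(
    assigned: Sequence[tuple[CanonicalFire, GeometryAssignment]],
    criteria_cfg: Optional[CriteriaConfig] = None,
) -> list[tuple[CanonicalFire, CriteriaFlags, GeometryAssignment]]:
    """Merge fires linked to the same perimeter into single observations.

    Connected components of the fire-perimeter linkage graph collapse to one
    record: geometry kept per tier precedence, harm counts maximized,
    ignition minimized, containment maximized, FMAG true if any member had
    one. Criteria flags are re-evaluated on the merged record.
    """
    graph = nx.Graph()
    graph.add_nodes_from(range(len(assigned)))
    by_perimeter: dict[tuple[str, str], list[int]] = {}
    for i, (_, assignment) in enumerate(assigned):
        if assignment.perimeter_key is not None:
            by_perimeter.setdefault(assignment.perimeter_key, []).append(i)
    for indices in by_perimeter.values():
        for a, b in zip(indices, indices[1:]):
            graph.add_edge(a, b)

    merged: list[tuple[CanonicalFire, CriteriaFlags, GeometryAssignment]] = []
    for component in sorted(nx.connected_components(graph), key=min):
        idx = sorted(component)
        fires = [assigned[i][0] for i in idx]
        assignments = [assigned[i][1] for i in idx]
        if len(idx) == 1:
            fire, assignment = fires[0], assignments[0]
        else:
            fire = _merge_fires(fires)
            assignment = min(
                assignments, key=lambda a: TIER_RANK[a.link_method]
            )
        merged.append((fire, evaluate_criteria(fire, criteria_cfg), assignment))
    merged.sort(key=lambda item: item[0].fire_id)
    return merged


def _merge_fires(fires: Sequence[CanonicalFire]) -> CanonicalFire:
    fires = sorted(fires, key=lambda f: f.fire_id)
    first = fires[0]

    def opt_max(attr):
        values = [getattr(f, attr) for f in fires if getattr(f, attr) is not None]
        return max(values) if values else None

    ignitions = [f.ignition_date for f in fires if f.ignition_date]
    containments = [f.containment_date for f in fires if f.containment_date]
    declarations = [
        f.fmag_declaration_date for f in fires if f.fmag_declaration_date
    ]
    origins = [f.origin for f in fires if f.origin is not None]
    years = [f.year for f in fires if f.year is not None]
    ignition = min(ignitions) if ignitions else None
    return CanonicalFire(
        fire_id=first.fire_id,
        names=tuple(sorted({n for f in fires for n in f.names})),
        counties=tuple(sorted({c for f in fires for c in f.counties})),
        ignition_date=ignition,
        containment_date=max(containments) if containments else None,
        year=ignition.year if ignition else (min(years) if years else None),
        civilian_fatalities=opt_max("civilian_fatalities"),
        total_fatalities=opt_max("total_fatalities"),
        destroyed_structures=opt_max("destroyed_structures"),
        damaged_structures=opt_max("damaged_structures"),
        combined_damaged_destroyed=opt_max("combined_damaged_destroyed"),
        fmag=any(f.fmag for f in fires),
        fmag_declaration_date=min(declarations) if declarations else None,
        origin=origins[0] if origins else None,
        area_acres=opt_max("area_acres"),
        shared_ids=tuple(sorted({s for f in fires for s in f.shared_ids})),
        threatened_structures=opt_max("threatened_structures"),
        injuries=opt_max("injuries"),
        evacuated=opt_max("evacuated"),
        estimated_cost=opt_max("estimated_cost"),
        members=tuple(sorted({m for f in fires for m in f.members})),
    )
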