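"""Final dataset output and summary statistics.

Writes the harmonized disaster records as a GeoJSON FeatureCollection (null
geometry allowed for county-level-only records) plus a machine-written
markdown data dictionary, and computes the summary tables: counts by year /
state / criterion / WUI class, percent shares (half-up to one decimal), and
the Mann-Kendall monotonic-trend statistic with tie-corrected variance.
"""

from __future__ import annotations

import datetime as dt
import itertools
import json
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import mapping, shape
from shapely.ops import transform

from .frames import LocalFrame
from .records import DisasterRecord, counties_from_str, counties_to_str


def summarize_counts(records: Sequence[DisasterRecord]) -> dict[str, pd.DataFrame]:
    """Count tables by year, state, criterion, and WUI class.

    Per-year counts key on the earliest ignition year. Records overlapping
    multiple states are counted once per state, so the state column total
    can exceed the record count.
    """
    years = [r.ignition_year for r in records if r.ignition_year is not None]
    by_year = (
        pd.Series(years, dtype=int).value_counts().sort_index().rename("n")
    )
    by_year = by_year.rename_axis("year").reset_index()

    state_rows = [s for r in records for s in r.states]
    by_state = (
        pd.Series(state_rows, dtype=object).value_counts().sort_index().rename("n")
    )
    by_state = by_state.rename_axis("state").reset_index()

    by_criterion = pd.DataFrame(
        [
            {"criterion": "fatality", "n": sum(r.fatality_met for r in records)},
            {"criterion": "structure", "n": sum(r.structure_met for r in records)},
            {"criterion": "fmag", "n": sum(r.fmag_met for r in records)},
        ]
    )

    wui = pd.Series([r.wui_class for r in records], dtype=object)
    by_wui = wui.value_counts().sort_index().rename("n").rename_axis("wui_class")
    return {
        "by_year": by_year,
        "by_state": by_state,
        "by_criterion": by_criterion,
        "by_wui": by_wui.reset_index(),
    }


def percent_share(numerator: int, denominator: int) -> float:
    """100 * numerator / denominator, rounded half-up to one decimal."""
    if denominator == 0:
        raise ZeroDivisionError("percent_share denominator is zero")
    ratio = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(ratio.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class TrendStats:
    n: int
    S: int
    var_S: float
    tau: float
    z: float
    p: float


def mann_kendall(series: Sequence[float], method: str = "normal") -> TrendStats:
    """Mann-Kendall monotonic trend statistic.

    ``S`` is the signed count over all ordered pairs, ``tau = S / (n(n-1)/2)``,
    and the variance carries the standard tie correction. The two-sided
    p-value uses the normal approximation with continuity correction, or an
    exact permutation enumeration for short series (``method="exact"``,
    n <= 10).
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("mann_kendall requires at least 3 observations")

    s = int(np.sign(x[None, :] - x[:, None])[np.triu_indices(n, k=1)].sum())
    n_pairs = n * (n - 1) // 2
    tau = s / n_pairs

    _, tie_counts = np.unique(x, return_counts=True)
    ties = tie_counts[tie_counts > 1]
    var_s = (
        n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))
    ) / 18.0

    if var_s > 0:
        if s > 0:
            z = (s - 1) / math.sqrt(var_s)
        elif s < 0:
            z = (s + 1) / math.sqrt(var_s)
        else:
            z = 0.0
    else:
        z = 0.0

    if method == "exact":
        if n > 10:
            raise ValueError("exact method limited to n <= 10")
        total = 0
        extreme = 0
        for perm in itertools.permutations(x):
            arr = np.asarray(perm)
            sp = int(
                np.sign(arr[None, :] - arr[:, None])[np.triu_indices(n, k=1)].sum()
            )
            total += 1
            extreme += abs(sp) >= abs(s)
        p = extreme / total
    else:
        p = 2.0 * (1.0 - stats.norm.cdf(abs(z)))
    return TrendStats(n=n, S=s, var_S=float(var_s), tau=tau, z=float(z), p=float(p))


# ---------------------------------------------------------------------------
# GeoJSON output
# ---------------------------------------------------------------------------

_FIELD_DOCS = {
    "fire_id": "Unique identifier of the incident/complex.",
    "names": "All standardized name variants observed across sources.",
    "counties": "All state:county combinations touched by the event.",
    "states": "States covered (derived from counties).",
    "ignition_date": "Earliest resolved ignition date (ISO).",
    "containment_date": "Latest resolved containment date (ISO).",
    "year": "Ignition year used for era rules.",
    "civilian_fatalities": "Resolved civilian fatality count.",
    "total_fatalities": "Resolved fatality count of any type.",
    "destroyed_structures": "Resolved destroyed-structure count.",
    "damaged_structures": "Resolved damaged-structure count.",
    "combined_damaged_destroyed": "Combined damaged/destroyed count (2007-2009 reporting).",
    "fmag": "Whether a federal fire-assistance declaration exists.",
    "fmag_declaration_date": "Earliest declaration date (ISO).",
    "origin_lon": "Reported point-of-origin longitude.",
    "origin_lat": "Reported point-of-origin latitude.",
    "area_acres": "Reported burn area in acres.",
    "area_km2": "Burn-zone area in km^2 (geometry or reported).",
    "threatened_structures": "Reported threatened structures (descriptive).",
    "injuries": "Reported injuries (descriptive).",
    "evacuated": "Reported people evacuated (descriptive).",
    "estimated_cost": "Estimated response cost in dollars (descriptive).",
    "fatality_met": "Fatality criterion flag.",
    "structure_met": "Destroyed-structure criterion flag.",
    "fmag_met": "Federal-assistance criterion flag.",
    "fatality_rule": "Which fatality rule fired (incl. era fallbacks).",
    "structure_rule": "Which structure rule fired (incl. era fallbacks).",
    "fmag_rule": "Which assistance rule fired.",
    "max_density": "Maximum smoothed population density in the buffered zone (people/km^2).",
    "mean_density": "Mean smoothed population density in the buffered zone (people/km^2).",
    "density_flag": "Maximum density >= threshold (null when no geometry).",
    "wui_class": "WUI overlap of the raw burn geometry: intermix|interface|both|none.",
    "community_flag": "Community proximity criterion (null when no geometry).",
    "is_disaster": "Harm criterion AND community criterion both met.",
    "geometry_source": "Provider of the burn geometry, or the fallback kind.",
    "link_method": "Tier used to link the geometry.",
}


def _record_properties(record: DisasterRecord, frame: LocalFrame) -> dict:
    origin_lon = origin_lat = None
    if record.origin is not None:
        origin_lon, origin_lat = frame.to_lonlat(*record.origin)
    return {
        "fire_id": record.fire_id,
        "names": list(record.names),
        "counties": counties_to_str(record.counties),
        "states": list(record.states),
        "ignition_date": _iso(record.ignition_date),
        "containment_date": _iso(record.containment_date),
        "year": record.year,
        "civilian_fatalities": record.civilian_fatalities,
        "total_fatalities": record.total_fatalities,
        "destroyed_structures": record.destroyed_structures,
        "damaged_structures": record.damaged_structures,
        "combined_damaged_destroyed": record.combined_damaged_destroyed,
        "fmag": record.fmag,
        "fmag_declaration_date": _iso(record.fmag_declaration_date),
        "origin_lon": origin_lon,
        "origin_lat": origin_lat,
        "area_acres": record.area_acres,
        "area_km2": record.area_km2,
        "threatened_structures": record.threatened_structures,
        "injuries": record.injuries,
        "evacuated": record.evacuated,
        "estimated_cost": record.estimated_cost,
        "fatality_met": record.fatality_met,
        "structure_met": record.structure_met,
        "fmag_met": record.fmag_met,
        "fatality_rule": record.fatality_rule,
        "structure_rule": record.structure_rule,
        "fmag_rule": record.fmag_rule,
        "max_density": _nan_to_none(record.max_density),
        "mean_density": _nan_to_none(record.mean_density),
        "density_flag": record.density_flag,
        "wui_class": record.wui_class,
        "community_flag": record.community_flag,
        "is_disaster": record.is_disaster,
        "geometry_source": record.geometry_source,
        "link_method": record.link_method,
    }


def _iso(d: Optional[dt.date]) -> Optional[str]:
    return None if d is None else d.isoformat()


def _nan_to_none(v: float) -> Optional[float]:
    return None if v is None or (isinstance(v, float) and math.isnan(v)) else v


def write_outputs(
    records: Sequence[DisasterRecord],
    path: str | Path,
    frame: Optional[LocalFrame] = None,
) -> None:
    """Write the dataset GeoJSON and a sibling markdown data dictionary.

    Coordinates are emitted as lon/lat (GeoJSON axis order); the planar
    working frame is inverted at this boundary only.
    """
    frame = frame or LocalFrame()
    path = Path(path)
    features = []
    for record in records:
        geometry = None
        if record.geometry is not None:
            geo = transform(
                lambda x, y: _lonlat_arrays(frame, x, y), record.geometry
            )
            geometry = mapping(geo)
        features.append(
            {
                "type": "Feature",
                "geometry": geometry,
                "properties": _record_properties(record, frame),
            }
        )
    collection = {"type": "FeatureCollection", "features": features}
    path.write_text(json.dumps(collection, indent=1, sort_keys=True))

    dictionary = ["# Data dictionary", ""]
    for name, doc in _FIELD_DOCS.items():
        dictionary.append(f"- **{name}**: {doc}")
    dictionary.append("")
    path.with_suffix(".dictionary.md").write_text("\n".join(dictionary))


def _lonlat_arrays(frame: LocalFrame, x, y):
    xs = np.atleast_1d(np.asarray(x, dtype=float))
    ys = np.atleast_1d(np.asarray(y, dtype=float))
    lons = np.empty_like(xs)
    lats = np.empty_like(ys)
    for i in range(len(xs)):
        lons[i], lats[i] = frame.to_lonlat(xs[i], ys[i])
    if np.isscalar(x):
        return lons[0], lats[0]
    return lons, lats


def read_outputs(
    path: str | Path, frame: Optional[LocalFrame] = None
) -> list[DisasterRecord]:
    """Read back a dataset GeoJSON written by :func:`write_outputs`."""
    frame = frame or LocalFrame()
    data = json.loads(Path(path).read_text())
    records = []
    for feature in data["features"]:
        props = feature["properties"]
        geometry = None
        if feature.get("geometry") is not None:
            geo = shape(feature["geometry"])
            geometry = transform(
                lambda lon, lat: _xy_arrays(frame, lon, lat), geo
            )
        origin = None
        if props.get("origin_lon") is not None:
            origin = frame.to_xy(props["origin_lon"], props["origin_lat"])
        records.append(
            DisasterRecord(
                fire_id=props["fire_id"],
                names=tuple(props["names"]),
                counties=counties_from_str(props["counties"]),
                ignition_date=_date(props.get("ignition_date")),
                containment_date=_date(props.get("containment_date")),
                year=props.get("year"),
                civilian_fatalities=props.get("civilian_fatalities"),
                total_fatalities=props.get("total_fatalities"),
                destroyed_structures=props.get("destroyed_structures"),
                damaged_structures=props.get("damaged_structures"),
                combined_damaged_destroyed=props.get("combined_damaged_destroyed"),
                fmag=props["fmag"],
                fmag_declaration_date=_date(props.get("fmag_declaration_date")),
                origin=origin,
                area_acres=props.get("area_acres"),
                area_km2=props.get("area_km2"),
                threatened_structures=props.get("threatened_structures"),
                injuries=props.get("injuries"),
                evacuated=props.get("evacuated"),
                estimated_cost=props.get("estimated_cost"),
                fatality_met=props["fatality_met"],
                structure_met=props["structure_met"],
                fmag_met=props["fmag_met"],
                fatality_rule=props["fatality_rule"],
                structure_rule=props["structure_rule"],
                fmag_rule=props["fmag_rule"],
                max_density=(
                    float("nan")
                    if props.get("max_density") is None
                    else props["max_density"]
                ),
                mean_density=(
                    float("nan")
                    if props.get("mean_density") is None
                    else props["mean_density"]
                ),
                density_flag=props.get("density_flag"),
                wui_class=props["wui_class"],
                community_flag=props.get("community_flag"),
                geometry=geometry,
                geometry_source=props["geometry_source"],
                link_method=props["link_method"],
            )
        )
    return records


def _xy_arrays(frame: LocalFrame, lon, lat):
    lons = np.atleast_1d(np.asarray(lon, dtype=float))
    lats = np.atleast_1d(np.asarray(lat, dtype=float))
    xs = np.empty_like(lons)
    ys = np.empty_like(lats)
    for i in range(len(lons)):
        xs[i], ys[i] = frame.to_xy(lons[i], lats[i])
    if np.isscalar(lon):
        return xs[0], ys[0]
    return xs, ys


def _date(v: Optional[str]) -> Optional[dt.date]:
    return None if v is None else dt.date.fromisoformat(v)
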