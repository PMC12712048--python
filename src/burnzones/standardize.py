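"""Name, county, and date standardization for incident source tables.

Cleans raw source-flavored tables into :class:`SourceEventRecord` lists:
normalizes incident names against a bundled USPS abbreviation table,
canonicalizes county names against a gazetteer, parses dates across the
dialects the sources use, and drops pre-2000 and non-fire rows with a
per-row rejection log.
"""

from __future__ import annotations

import datetime as dt
import json
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional

import pandas as pd
from shapely.geometry.base import BaseGeometry

from .records import UNRESOLVED, SourceEventRecord

_NON_ALNUM = re.compile(r"[^A-Z0-9]+")


def load_usps_table() -> dict[str, str]:
    """Bundled USPS whole-word abbreviation table (versioned fixture)."""
    text = (
        resources.files("burnzones.data")
        .joinpath("usps_abbreviations.json")
        .read_text()
    )
    return json.loads(text)["abbreviations"]


_USPS = None


def _usps() -> dict[str, str]:
    global _USPS
    if _USPS is None:
        _USPS = load_usps_table()
    return _USPS


def standardize_name(raw: str, table: Optional[dict[str, str]] = None) -> str:
    """Uppercase, strip punctuation, abbreviate whole tokens, collapse spaces.

    Only whole tokens are replaced (never substrings), so e.g. MOUNTAINEER
    is left intact while MOUNTAIN becomes MTN. Idempotent: abbreviations are
    never themselves table keys.
    """
    if table is None:
        table = _usps()
    tokens = _NON_ALNUM.sub(" ", str(raw).upper()).split()
    return " ".join(table.get(t, t) for t in tokens)


DEFAULT_COUNTY_ALIASES: dict[str, str] = {"LA": "LOS ANGELES"}


@dataclass
class Gazetteer:
    """Canonical county names (and optionally polygons) per state."""

    counties: dict[str, dict[str, Optional[BaseGeometry]]]
    aliases: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_COUNTY_ALIASES))
    la_alias_enabled: bool = True

    def states(self) -> tuple[str, ...]:
        return tuple(sorted(self.counties))

    def names(self, state: str) -> tuple[str, ...]:
        if state not in self.counties:
            raise KeyError(f"unknown state {state!r}")
        return tuple(sorted(self.counties[state]))

    def geometry(self, state: str, county: str) -> Optional[BaseGeometry]:
        return self.counties[state].get(county)

    def resolve(self, raw: str, state: str) -> str:
        """Canonical county name, or the unresolved sentinel (record kept)."""
        if state not in self.counties:
            raise KeyError(f"unknown state {state!r}")
        name = standardize_name(raw, table={})
        # strip a trailing COUNTY / CO qualifier
        for suffix in (" COUNTY", " CO"):
            if name.endswith(suffix):
                name = name[: -len(suffix)]
        if name in self.counties[state]:
            return name
        if self.la_alias_enabled and name in self.aliases:
            alias = self.aliases[name]
            if alias in self.counties[state]:
                return alias
        return UNRESOLVED


@dataclass
class CleanConfig:
    min_year: int = 2000
    nonfire_patterns: tuple[str, ...] = ("COVID",)
    redbooks_state: str = "CA"
    date_formats: tuple[str, ...] = ("%Y-%m-%d", "%m/%d/%Y", "%m/%d/%y")


def parse_date(value, formats: Iterable[str]) -> Optional[dt.date]:
    """Parse a date string across the configured dialects; None if blank."""
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    text = str(value).strip()
    for fmt in formats:
        try:
            return dt.datetime.strptime(text, fmt).date()
        except ValueError:
            continue
    raise ValueError(f"unparseable date {value!r}")


def _opt_count(value) -> Optional[int]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    n = int(value)
    if n < 0:
        raise ValueError(f"negative count {value!r}")
    return n


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return float(value)


def _clean_counties(
    raw_counties, state: str, gazetteer: Optional[Gazetteer]
) -> tuple[tuple[str, str], ...]:
    """All (state, county) combinations for a possibly multi-valued field."""
    if raw_counties is None or (
        isinstance(raw_counties, float) and pd.isna(raw_counties)
    ):
        return ()
    parts = [p for p in re.split(r"[;,|]", str(raw_counties)) if p.strip()]
    out = []
    for part in parts:
        if gazetteer is not None and state in gazetteer.counties:
            out.append((state, gazetteer.resolve(part, state)))
        else:
            out.append((state, standardize_name(part, table={})))
    return tuple(dict.fromkeys(out))


def clean_events(
    table: pd.DataFrame,
    source: str,
    gazetteer: Optional[Gazetteer] = None,
    config: Optional[CleanConfig] = None,
) -> tuple[list[SourceEventRecord], pd.DataFrame]:
    """Clean one raw source-flavored table.

    Returns cleaned records plus a rejection log with one row per dropped
    input row (columns: source, source_id, reason). Row conservation holds:
    ``len(table) == len(records) + len(rejections)``.
    """
    cfg = config or CleanConfig()
    records: list[SourceEventRecord] = []
    rejections: list[dict] = []

    name_col = {"ics209": "incident_name", "redbooks": "fire_name", "fmag": "incident_name"}[source]
    id_col = {"ics209": "source_id", "redbooks": "source_id", "fmag": "declaration_id"}[source]

    for row in table.to_dict("records"):
        source_id = str(row.get(id_col, ""))

        def reject(reason: str) -> None:
            rejections.append(
                {"source": source, "source_id": source_id, "reason": reason}
            )

        raw_name = str(row.get(name_col, ""))
        clean_name = standardize_name(raw_name)
        if any(pat.upper() in clean_name for pat in cfg.nonfire_patterns):
            reject("non-fire")
            continue

        try:
            ignition = parse_date(row.get("ignition_date"), cfg.date_formats)
            containment = parse_date(row.get("containment_date"), cfg.date_formats)
            declaration = parse_date(
                row.get("declaration_date"), cfg.date_formats
            )
        except ValueError:
            reject("unparseable-date")
            continue

        year = row.get("year")
        year = None if year is None or pd.isna(year) else int(year)
        if year is None and ignition is not None:
            year = ignition.year
        elif ignition is not None:
            year = ignition.year  # ignition date is authoritative for the year
        if year is None:
            reject("missing-year")
            continue
        if year < cfg.min_year:
            reject("pre-2000")
            continue

        state = row.get("state")
        if source == "redbooks" or state is None or pd.isna(state):
            # Redbooks rows carry no state; all are assigned the configured one.
            state = cfg.redbooks_state if source == "redbooks" else state
        if state is None or pd.isna(state):
            counties: tuple[tuple[str, str], ...] = ()
        else:
            counties = _clean_counties(row.get("county"), str(state), gazetteer)
            if not counties:
                counties = ((str(state), UNRESOLVED),)

        origin = None
        if _opt_float(row.get("origin_x")) is not None:
            origin = (float(row["origin_x"]), float(row["origin_y"]))

        try:
            record = SourceEventRecord(
                source=source,
                source_id=source_id,
                raw_name=raw_name,
                clean_name=clean_name,
                counties=counties,
                ignition_date=ignition,
                containment_date=containment,
                year=year,
                civilian_fatalities=_opt_count(row.get("civilian_fatalities")),
                total_fatalities=_opt_count(row.get("total_fatalities")),
                destroyed_structures=_opt_count(row.get("destroyed_structures")),
                damaged_structures=_opt_count(row.get("damaged_structures")),
                combined_damaged_destroyed=_opt_count(
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
                fmag_declaration_date=declaration,
                threatened_structures=_opt_count(row.get("threatened_structures")),
                injuries=_opt_count(row.get("injuries")),
                evacuated=_opt_count(row.get("evacuated")),
                estimated_cost=_opt_float(row.get("estimated_cost")),
                truth_id=(
                    None
                    if row.get("truth_id") is None
                    or (isinstance(row.get("truth_id"), float) and pd.isna(row["truth_id"]))
                    else str(row["truth_id"])
                ),
            )
        except ValueError as err:
            reject(f"invalid-value: {err}")
            continue
        records.append(record)

    rejection_log = pd.DataFrame(
        rejections, columns=["source", "source_id", "reason"]
    )
    return records, rejection_log
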