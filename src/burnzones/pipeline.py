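"""End-to-end orchestration: simulate -> clean -> link -> criteria ->
geolink -> community -> report.

Each stage writes a plain-text artifact (CSV / GeoJSON / ASCII grid) into
the working directory and the audit report reconciles record counts across
stages. A manifest keyed by the config hash makes whole-pipeline re-runs
with an unchanged config reuse the existing outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
from shapely.geometry import mapping, shape

from . import synthetic
from .community import CommunityConfig, classify_community, epoch_for_year, smooth_density
from .criteria import CriteriaConfig, filter_preliminary
from .frames import LocalFrame
from .geolink import GeoLinkConfig, assign_geometry, merge_linked_groups
from .grids import Grid, read_ascii, write_ascii
from .linkage import MatchConfig, ResolveConfig, cluster_events, resolve_all
from .records import (
    DisasterRecord,
    PerimeterRecord,
    events_from_frame,
    events_to_frame,
)
from .report import summarize_counts, write_outputs
from .standardize import CleanConfig, Gazetteer, clean_events, standardize_name
from .synthetic import SimulationConfig, SyntheticWorld, classify_wui

logger = logging.getLogger("burnzones")


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    clean: CleanConfig = field(default_factory=CleanConfig)
    match: MatchConfig = field(default_factory=MatchConfig)
    resolve: ResolveConfig = field(default_factory=ResolveConfig)
    criteria: CriteriaConfig = field(default_factory=CriteriaConfig)
    geolink: GeoLinkConfig = field(default_factory=GeoLinkConfig)
    community: CommunityConfig = field(default_factory=CommunityConfig)
    seed: int = 0

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


# ---------------------------------------------------------------------------
# perimeter GeoJSON I/O (planar coordinates stay internal; files carry lon/lat)
# ---------------------------------------------------------------------------


def write_perimeters(
    records: list[PerimeterRecord], path: Path, frame: LocalFrame
) -> None:
    from .report import _lonlat_arrays
    from shapely.ops import transform

    features = []
    for r in records:
        geo = transform(lambda x, y: _lonlat_arrays(frame, x, y), r.geometry)
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(geo),
                "properties": {
                    "flavor": r.flavor,
                    "perimeter_id": r.perimeter_id,
                    "name": r.name,
                    "shared_id": r.shared_id,
                    "ignition_date": None if r.ignition_date is None else r.ignition_date.isoformat(),
                    "containment_date": None if r.containment_date is None else r.containment_date.isoformat(),
                    "year": r.year,
                    "area_acres": r.area_acres,
                    "truth_id": r.truth_id,
                },
            }
        )
    path.write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, sort_keys=True)
    )


def read_perimeters(path: Path, frame: LocalFrame) -> list[PerimeterRecord]:
    import datetime as dt

    from shapely.ops import transform

    from .geolink import repair_geometry
    from .report import _xy_arrays

    data = json.loads(path.read_text())
    records = []
    for feature in data["features"]:
        props = feature["properties"]
        geom = transform(
            lambda lon, lat: _xy_arrays(frame, lon, lat), shape(feature["geometry"])
        )
        records.append(
            PerimeterRecord(
                flavor=props["flavor"],
                perimeter_id=props["perimeter_id"],
                geometry=repair_geometry(geom),
                area_acres=props["area_acres"],
                name=None if props.get("name") is None else standardize_name(props["name"]),
                shared_id=props.get("shared_id"),
                ignition_date=(
                    None
                    if props.get("ignition_date") is None
                    else dt.date.fromisoformat(props["ignition_date"])
                ),
                containment_date=(
                    None
                    if props.get("containment_date") is None
                    else dt.date.fromisoformat(props["containment_date"])
                ),
                year=props.get("year"),
                truth_id=props.get("truth_id"),
            )
        )
    return records


def write_counties(world: SyntheticWorld, path: Path) -> None:
    from shapely.ops import transform

    from .report import _lonlat_arrays

    features = []
    for county in world.counties:
        geo = transform(
            lambda x, y: _lonlat_arrays(world.frame, x, y), county.polygon
        )
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(geo),
                "properties": {"state": county.state, "county": county.name},
            }
        )
    path.write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, sort_keys=True)
    )


def _project_origins(frame: LocalFrame, table: pd.DataFrame) -> pd.DataFrame:
    """Add planar origin_x/origin_y columns from lon/lat at ingestion."""
    table = table.copy()
    xs, ys = [], []
    for lon, lat in zip(table.get("origin_lon", []), table.get("origin_lat", [])):
        if lon is None or pd.isna(lon):
            xs.append(None)
            ys.append(None)
        else:
            x, y = frame.to_xy(float(lon), float(lat))
            xs.append(x)
            ys.append(y)
    if xs:
        table["origin_x"] = xs
        table["origin_y"] = ys
    return table


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    records: list[DisasterRecord]
    audit: dict
    workdir: Path


def run_pipeline(
    config: Optional[PipelineConfig] = None,
    workdir: str | Path = "pipeline_out",
    use_cache: bool = True,
) -> PipelineResult:
    """Run every stage end to end; deterministic for a fixed config.

    The final GeoJSON keeps *all* criterion-meeting fires; the flagged
    disaster subset additionally requires the community criterion (records
    without geometry keep a null community flag and stay unflagged).
    """
    cfg = config or PipelineConfig()
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    manifest_path = workdir / "manifest.json"
    digest = cfg.digest()
    final_path = workdir / "disasters.geojson"
    if use_cache and manifest_path.exists() and final_path.exists():
        manifest = json.loads(manifest_path.read_text())
        if manifest.get("digest") == digest:
            logger.info("config unchanged; reusing cached pipeline outputs")
            from .report import read_outputs

            frame = LocalFrame(
                cfg.simulation.world.lon0, cfg.simulation.world.lat0
            )
            return PipelineResult(
                records=read_outputs(final_path, frame),
                audit=json.loads((workdir / "audit.json").read_text()),
                workdir=workdir,
            )

    audit: dict = {"stages": {}}

    # --- simulate -----------------------------------------------------------
    logger.info("stage simulate")
    world, fires = synthetic.generate_truth(cfg.simulation, cfg.seed)
    gazetteer = world.gazetteer()
    write_counties(world, workdir / "counties.geojson")
    raw_tables = {}
    for flavor in ("ics209", "redbooks", "fmag"):
        table = synthetic.render_sources(
            fires, flavor, cfg.simulation.noise, cfg.seed, cfg.simulation, world
        )
        table.to_csv(workdir / f"raw_{flavor}.csv", index=False)
        raw_tables[flavor] = table
    perimeters = {}
    for flavor in ("mtbs", "fired", "nifc"):
        records = synthetic.render_perimeters(fires, flavor, cfg.seed, cfg.simulation)
        write_perimeters(records, workdir / f"perimeters_{flavor}.geojson", world.frame)
        perimeters[flavor] = records
    audit["stages"]["simulate"] = {
        "n_truth_fires": len(fires),
        **{f"rows_{k}": len(v) for k, v in raw_tables.items()},
        **{f"perimeters_{k}": len(v) for k, v in perimeters.items()},
    }

    # --- clean --------------------------------------------------------------
    logger.info("stage clean")
    cleaned = []
    rejection_frames = []
    for flavor, table in raw_tables.items():
        table = _project_origins(world.frame, table)
        records, rejections = clean_events(table, flavor, gazetteer, cfg.clean)
        cleaned.append(records)
        rejection_frames.append(rejections)
        if len(records) + len(rejections) != len(table):
            raise RuntimeError(f"clean stage lost rows for {flavor}")
    rejection_log = pd.concat(rejection_frames, ignore_index=True)
    rejection_log.to_csv(workdir / "rejections.csv", index=False)
    all_records = [r for table in cleaned for r in table]
    events_to_frame(all_records).to_csv(workdir / "cleaned_events.csv", index=False)
    audit["stages"]["clean"] = {
        "rows_in": int(sum(len(t) for t in raw_tables.values())),
        "rows_out": len(all_records),
        "rows_rejected": len(rejection_log),
    }

    # --- link ---------------------------------------------------------------
    logger.info("stage link")
    clusters = cluster_events(cleaned, cfg.match)
    canonical = resolve_all(clusters, all_records, cfg.resolve)
    membership = pd.DataFrame(
        [
            {"fire_id": fire.fire_id, "source": s, "source_id": sid}
            for fire in canonical
            for (s, sid) in fire.members
        ]
    )
    membership.to_csv(workdir / "cluster_membership.csv", index=False)
    if len(membership) != len(all_records):
        raise RuntimeError("linkage stage lost rows")
    audit["stages"]["link"] = {
        "records_in": len(all_records),
        "canonical_fires": len(canonical),
    }

    # --- criteria -----------------------------------------------------------
    logger.info("stage criteria")
    preliminary, criterion_counts = filter_preliminary(canonical, cfg.criteria)
    audit["stages"]["criteria"] = {
        "canonical_in": len(canonical),
        "preliminary": len(preliminary),
        **criterion_counts,
    }

    # --- geolink ------------------------------------------------------------
    logger.info("stage geolink")
    assigned = []
    geolink_rejects = 0
    for fire, flags in preliminary:
        try:
            assignment = assign_geometry(fire, perimeters, gazetteer, cfg.geolink)
        except ValueError:
            geolink_rejects += 1
            continue
        assigned.append((fire, assignment))
    merged = merge_linked_groups(assigned, cfg.criteria)
    pd.DataFrame(
        [
            {
                "fire_id": fire.fire_id,
                "link_method": a.link_method,
                "geometry_source": a.geometry_source,
            }
            for fire, _, a in merged
        ]
    ).to_csv(workdir / "geometry_assignments.csv", index=False)
    audit["stages"]["geolink"] = {
        "preliminary_in": len(preliminary),
        "rejected_no_location": geolink_rejects,
        "assigned": len(assigned),
        "merged_out": len(merged),
        "merged_away": len(assigned) - len(merged),
        "tiers": {
            k: int(v)
            for k, v in pd.Series([a.link_method for _, _, a in merged])
            .value_counts()
            .sort_index()
            .items()
        },
    }

    # --- community ----------------------------------------------------------
    logger.info("stage community")
    epochs = sorted(
        {
            epoch_for_year(fire.ignition_year or 2000, cfg.community.epoch_interval)
            for fire, _, _ in merged
        }
    )
    smoothed: dict[int, Grid] = {}
    for epoch in epochs:
        pop = synthetic.generate_population_grid(world, epoch)
        smoothed[epoch] = smooth_density(pop, cfg.community.smoothing_radius_m)
    write_ascii(
        synthetic.generate_population_grid(world, epochs[0]),
        workdir / f"population_{epochs[0]}.asc",
        fmt="%d",
    )
    wui = classify_wui(world.housing, world.vegetation)
    write_ascii(wui.classes, workdir / "wui.asc", fmt="%d")

    records: list[DisasterRecord] = []
    for fire, flags, assignment in merged:
        year = fire.ignition_year
        epoch = epoch_for_year(year or 2000, cfg.community.epoch_interval)
        exposure = classify_community(
            assignment, wui.classes, smoothed[epoch], year, cfg.community
        )
        records.append(
            DisasterRecord(
                fire_id=fire.fire_id,
                names=fire.names,
                counties=fire.counties,
                ignition_date=fire.ignition_date,
                containment_date=fire.containment_date,
                year=year,
                civilian_fatalities=fire.civilian_fatalities,
                total_fatalities=fire.total_fatalities,
                destroyed_structures=fire.destroyed_structures,
                damaged_structures=fire.damaged_structures,
                combined_damaged_destroyed=fire.combined_damaged_destroyed,
                fmag=fire.fmag,
                fmag_declaration_date=fire.fmag_declaration_date,
                origin=fire.origin,
                area_acres=fire.area_acres,
                area_km2=assignment.area_km2,
                threatened_structures=fire.threatened_structures,
                injuries=fire.injuries,
                evacuated=fire.evacuated,
                estimated_cost=fire.estimated_cost,
                fatality_met=flags.fatality_met,
                structure_met=flags.structure_met,
                fmag_met=flags.fmag_met,
                fatality_rule=flags.fatality_rule,
                structure_rule=flags.structure_rule,
                fmag_rule=flags.fmag_rule,
                max_density=exposure.max_density,
                mean_density=exposure.mean_density,
                density_flag=exposure.density_flag,
                wui_class=exposure.wui_class,
                community_flag=exposure.community_flag,
                geometry=assignment.geometry,
                geometry_source=assignment.geometry_source,
                link_method=assignment.link_method,
            )
        )
    audit["stages"]["community"] = {
        "records": len(records),
        "flagged_disasters": sum(r.is_disaster for r in records),
        "community_unknown": sum(r.community_flag is None for r in records),
    }

    # --- report -------------------------------------------------------------
    logger.info("stage report")
    write_outputs(records, final_path, world.frame)
    tables = summarize_counts(records)
    for name, table in tables.items():
        table.to_csv(workdir / f"summary_{name}.csv", index=False)

    audit["checks"] = _audit_checks(records, audit)
    (workdir / "audit.json").write_text(json.dumps(audit, indent=1, sort_keys=True))
    _write_audit_markdown(audit, workdir / "audit.md")
    manifest_path.write_text(
        json.dumps({"digest": digest, "seed": cfg.seed}, indent=1)
    )
    return PipelineResult(records=records, audit=audit, workdir=workdir)


def _audit_checks(records: list[DisasterRecord], audit: dict) -> dict:
    definition_ok = all(
        (r.fatality_met or r.structure_met or r.fmag_met) and r.community_flag
        for r in records
        if r.is_disaster
    ) and all(
        not r.is_disaster
        for r in records
        if not (
            (r.fatality_met or r.structure_met or r.fmag_met)
            and r.community_flag
        )
    )
    community_identity_ok = all(
        r.community_flag == (bool(r.density_flag) or r.wui_class != "none")
        for r in records
        if r.community_flag is not None
    )
    stages = audit["stages"]
    conservation_ok = (
        stages["clean"]["rows_in"]
        == stages["clean"]["rows_out"] + stages["clean"]["rows_rejected"]
    ) and (
        stages["geolink"]["preliminary_in"]
        == stages["geolink"]["merged_out"]
        + stages["geolink"]["merged_away"]
        + stages["geolink"]["rejected_no_location"]
    )
    return {
        "definition_ok": definition_ok,
        "community_identity_ok": community_identity_ok,
        "conservation_ok": conservation_ok,
    }


def _write_audit_markdown(audit: dict, path: Path) -> None:
    lines = ["# Pipeline audit", ""]
    for stage, stats in audit["stages"].items():
        lines.append(f"## {stage}")
        for key, value in stats.items():
            lines.append(f"- {key}: {value}")
        lines.append("")
    lines.append("## checks")
    for key, value in audit["checks"].items():
        lines.append(f"- {key}: {'PASS' if value else 'FAIL'}")
    lines.append("")
    path.write_text("\n".join(lines))
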