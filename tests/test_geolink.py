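import datetime as dt
import math

import numpy as np
import pytest
from shapely.geometry import MultiPolygon, Point, Polygon, box

from burnzones.frames import acres_to_m2
from burnzones.geolink import (
    GeoLinkConfig,
    assign_geometry,
    circle_from_point,
    merge_linked_groups,
    repair_geometry,
)
from burnzones.records import CanonicalFire, GeometryAssignment, PerimeterRecord
from burnzones.standardize import Gazetteer


class TestCircleFromPoint:
    def test_unit_radius_closed_form(self):
        # area pi km^2 -> radius exactly 1 km
        area_acres = math.pi * 1e6 / acres_to_m2(1.0)
        circle = circle_from_point((0.0, 0.0), area_acres)
        minx, miny, maxx, maxy = circle.bounds
        assert (maxx - minx) / 2 == pytest.approx(1000.0, rel=1e-3)
        assert circle.area == pytest.approx(math.pi * 1e6, rel=0.01)

    def test_thousand_acres_radius(self):
        # 1,000 acres = 4.0469 km^2 -> r = sqrt(A/pi) = 1.1349 km
        circle = circle_from_point((0.0, 0.0), 1000.0)
        minx, _, maxx, _ = circle.bounds
        assert (maxx - minx) / 2 == pytest.approx(1134.9, abs=1.0)

    def test_area_identity_random_areas(self):
        rng = np.random.default_rng(0)
        for area in rng.uniform(5.0, 100_000.0, size=50):
            circle = circle_from_point((0.0, 0.0), float(area))
            target = acres_to_m2(float(area))
            assert abs(circle.area - target) / target < 0.01

    def test_absent_area_returns_point(self):
        geom = circle_from_point((5.0, 6.0), None)
        assert isinstance(geom, Point) and (geom.x, geom.y) == (5.0, 6.0)

    @pytest.mark.parametrize("bad", [-1.0, 0.0, float("nan"), float("inf")])
    def test_invalid_area_raises(self, bad):
        with pytest.raises(ValueError):
            circle_from_point((0.0, 0.0), bad)


def test_repair_geometry_casts_to_multipolygon():
    bowtie = Polygon([(0, 0), (2, 2), (2, 0), (0, 2)])  # self-intersecting
    repaired = repair_geometry(bowtie)
    assert isinstance(repaired, MultiPolygon) and repaired.is_valid
    plain = repair_geometry(box(0, 0, 1, 1))
    assert isinstance(plain, MultiPolygon)


def _fire(**kwargs):
    defaults = dict(
        fire_id="F0",
        names=("CEDAR",),
        counties=(("CA", "KERN"),),
        ignition_date=dt.date(2010, 6, 1),
        year=2010,
        origin=(50_000.0, 50_000.0),
        area_acres=500.0,
    )
    defaults.update(kwargs)
    return CanonicalFire(**defaults)


def _perimeter(flavor="mtbs", pid="P0", geom=None, **kwargs):
    defaults = dict(
        area_acres=500.0,
        name="CEDAR",
        ignition_date=dt.date(2010, 6, 1),
    )
    defaults.update(kwargs)
    return PerimeterRecord(
        flavor=flavor,
        perimeter_id=pid,
        geometry=geom or box(49_000, 49_000, 51_000, 51_000),
        **defaults,
    )


@pytest.fixture
def gazetteer():
    return Gazetteer(
        counties={"CA": {"KERN": box(0, 0, 100_000, 100_000), "MONO": None}}
    )


class TestAssignGeometry:
    def test_tier1_shared_id(self, gazetteer):
        perim = _perimeter(shared_id="IRW-1", name="TOTALLY DIFFERENT")
        fire = _fire(shared_ids=("IRW-1",))
        a = assign_geometry(fire, {"mtbs": [perim]}, gazetteer)
        assert a.link_method == "shared_id" and a.geometry_source == "mtbs"
        assert a.geometry.equals(repair_geometry(perim.geometry))

    def test_tier2_mtbs_name_date_location(self, gazetteer):
        perim = _perimeter(ignition_date=dt.date(2010, 6, 20))
        a = assign_geometry(_fire(), {"mtbs": [perim]}, gazetteer)
        assert a.link_method == "mtbs_name"

    def test_tier2_rejects_31_day_gap(self, gazetteer):
        perim = _perimeter(ignition_date=dt.date(2010, 7, 2))
        a = assign_geometry(_fire(), {"mtbs": [perim]}, gazetteer)
        assert a.link_method == "circular_buffer"

    def test_tier2_rejects_dissimilar_name(self, gazetteer):
        perim = _perimeter(name="GRANITE GORGE")
        a = assign_geometry(_fire(), {"mtbs": [perim]}, gazetteer)
        assert a.link_method == "circular_buffer"

    def test_tier2_rejects_distant_origin(self, gazetteer):
        far = _perimeter(geom=box(80_000, 80_000, 82_000, 82_000))
        a = assign_geometry(_fire(), {"mtbs": [far]}, gazetteer)
        assert a.link_method == "circular_buffer"

    def test_fired_origin_tier(self, gazetteer):
        perim = _perimeter(flavor="fired", name=None)
        a = assign_geometry(_fire(), {"fired": [perim]}, gazetteer)
        assert a.link_method == "fired_origin" and a.geometry_source == "fired"

    def test_nifc_year_window(self, gazetteer):
        perim = _perimeter(flavor="nifc", ignition_date=None, year=2010)
        a = assign_geometry(_fire(), {"nifc": [perim]}, gazetteer)
        assert a.link_method == "nifc_name"
        # 30 days beyond the year boundary still matches
        early = _fire(ignition_date=dt.date(2011, 1, 25), year=2011)
        assert assign_geometry(early, {"nifc": [perim]}, gazetteer).link_method == "nifc_name"
        late = _fire(ignition_date=dt.date(2011, 3, 1), year=2011)
        assert assign_geometry(late, {"nifc": [perim]}, gazetteer).link_method != "nifc_name"

    def test_circular_buffer_fallback(self, gazetteer):
        a = assign_geometry(_fire(), {}, gazetteer)
        assert a.link_method == "circular_buffer"
        target = acres_to_m2(500.0)
        assert abs(a.geometry.area - target) / target < 0.01
        assert a.area_km2 == pytest.approx(target / 1e6, rel=0.01)

    def test_point_only_when_area_missing(self, gazetteer):
        a = assign_geometry(_fire(area_acres=None), {}, gazetteer)
        assert a.link_method == "point_only"
        assert isinstance(a.geometry, Point) and a.area_km2 is None

    def test_county_only_without_origin(self, gazetteer):
        a = assign_geometry(_fire(origin=None, area_acres=None), {}, gazetteer)
        assert a.link_method == "county_only" and a.geometry is None

    def test_rejected_without_origin_or_county(self, gazetteer):
        fire = _fire(origin=None, area_acres=None, counties=())
        with pytest.raises(ValueError):
            assign_geometry(fire, {}, gazetteer)

    def test_tier_exclusivity_on_synthetic_world(self, sim_config, small_world):
        # every preliminary fire gets exactly one link method, and tier-1
        # matches return the truth perimeter exactly
        from burnzones import synthetic as syn
        from burnzones.linkage import cluster_events, resolve_all
        from burnzones.standardize import clean_events
        from burnzones.pipeline import _project_origins

        world, fires = small_world
        gaz = world.gazetteer()
        tables = []
        for flavor in ("ics209", "redbooks", "fmag"):
            frame = syn.render_sources(fires, flavor, sim_config.noise, 7, sim_config, world)
            frame = _project_origins(world.frame, frame)
            records, _ = clean_events(frame, flavor, gaz)
            tables.append(records)
        all_records = [r for t in tables for r in t]
        canonical = resolve_all(cluster_events(tables), all_records)
        perims = {
            fl: syn.render_perimeters(fires, fl, 7, sim_config)
            for fl in ("mtbs", "fired", "nifc")
        }
        truth_geom = {f.truth_id: f.perimeter for f in fires}
        by_key = {p.perimeter_id: p for ps in perims.values() for p in ps}
        n_assigned = 0
        for fire in canonical:
            a = assign_geometry(fire, perims, gaz)
            n_assigned += 1
            if a.link_method == "shared_id":
                perim = by_key[a.perimeter_key[1]]
                assert a.geometry.equals(repair_geometry(truth_geom[perim.truth_id]))
        assert n_assigned == len(canonical)


class TestMergeLinkedGroups:
    def test_disjoint_linkage_merge(self):
        shared = GeometryAssignment(
            geometry=repair_geometry(box(0, 0, 1000, 1000)),
            geometry_source="mtbs",
            link_method="mtbs_name",
            area_km2=1.0,
            perimeter_key=("mtbs", "P0"),
        )
        a = _fire(fire_id="FA", destroyed_structures=2, fmag=False)
        b = _fire(
            fire_id="FB",
            destroyed_structures=7,
            fmag=True,
            ignition_date=dt.date(2010, 5, 20),
        )
        merged = merge_linked_groups([(a, shared), (b, shared)])
        assert len(merged) == 1
        fire, flags, assignment = merged[0]
        assert fire.destroyed_structures == 7  # max across the group
        assert fire.fmag and flags.fmag_met
        assert fire.ignition_date == dt.date(2010, 5, 20)
        assert assignment.perimeter_key == ("mtbs", "P0")

    def test_max_of_three(self):
        shared = GeometryAssignment(
            geometry=repair_geometry(box(0, 0, 1000, 1000)),
            geometry_source="mtbs",
            link_method="mtbs_name",
            area_km2=1.0,
            perimeter_key=("mtbs", "P0"),
        )
        fires = [
            (_fire(fire_id=f"F{i}", destroyed_structures=n), shared)
            for i, n in enumerate([2, 7, 5])
        ]
        merged = merge_linked_groups(fires)
        assert len(merged) == 1
        assert merged[0][0].destroyed_structures == 7

    def test_no_shared_perimeters_unchanged(self):
        own = lambda pid: GeometryAssignment(
            geometry=repair_geometry(box(0, 0, 1000, 1000)),
            geometry_source="mtbs",
            link_method="mtbs_name",
            area_km2=1.0,
            perimeter_key=("mtbs", pid),
        )
        merged = merge_linked_groups(
            [(_fire(fire_id="FA"), own("P0")), (_fire(fire_id="FB"), own("P1"))]
        )
        assert len(merged) == 2

    def test_geometry_kept_by_tier_precedence(self):
        high = GeometryAssignment(
            geometry=repair_geometry(box(0, 0, 1000, 1000)),
            geometry_source="mtbs",
            link_method="shared_id",
            area_km2=1.0,
            perimeter_key=("mtbs", "P0"),
        )
        low = GeometryAssignment(
            geometry=repair_geometry(box(0, 0, 2000, 2000)),
            geometry_source="nifc",
            link_method="nifc_name",
            area_km2=4.0,
            perimeter_key=("mtbs", "P0"),
        )
        merged = merge_linked_groups(
            [(_fire(fire_id="FA"), low), (_fire(fire_id="FB"), high)]
        )
        assert merged[0][2].link_method == "shared_id"
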