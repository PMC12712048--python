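import dataclasses
import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest

from burnzones import synthetic as syn
from burnzones.frames import acres_to_m2
from burnzones.grids import Grid
from burnzones.standardize import standardize_name


def _fire_fingerprint(fire):
    d = dataclasses.asdict(fire)
    d["perimeter"] = fire.perimeter.wkt
    return d


class TestGenerateTruth:
    def test_deterministic_registries(self, sim_config):
        w1, f1 = syn.generate_truth(sim_config, seed=7)
        w2, f2 = syn.generate_truth(sim_config, seed=7)
        assert [_fire_fingerprint(a) for a in f1] == [_fire_fingerprint(b) for b in f2]
        assert np.array_equal(w1.vegetation.values, w2.vegetation.values)

    def test_different_seeds_differ(self, sim_config):
        _, f1 = syn.generate_truth(sim_config, seed=7)
        _, f2 = syn.generate_truth(sim_config, seed=8)
        assert [_fire_fingerprint(a) for a in f1] != [_fire_fingerprint(b) for b in f2]

    def test_exact_count_and_date_order(self):
        cfg = syn.SimulationConfig()
        cfg.fires.n_fires = 100
        _, fires = syn.generate_truth(cfg, seed=3)
        assert len(fires) == 100
        assert all(f.containment_date >= f.ignition_date for f in fires)
        assert all(2000 <= f.ignition_date.year <= 2025 for f in fires)

    def test_origin_inside_listed_counties(self, small_world):
        from shapely.geometry import Point

        world, fires = small_world
        lookup = {(c.state, c.name): c.polygon for c in world.counties}
        for fire in fires:
            assert any(
                lookup[pair].covers(Point(fire.origin)) for pair in fire.counties
            )

    def test_perimeter_area_within_one_percent(self, small_world):
        _, fires = small_world
        for fire in fires:
            target = acres_to_m2(fire.area_acres)
            assert abs(fire.perimeter.area - target) / target < 0.01

    def test_fatality_rate_binomial(self):
        cfg = syn.SimulationConfig()
        cfg.fires.n_fires = 1000
        cfg.fires.p_civilian_fatality = 0.1
        _, fires = syn.generate_truth(cfg, seed=11)
        n_fatal = sum(f.civilian_fatalities >= 1 for f in fires)
        sd = math.sqrt(1000 * 0.1 * 0.9)
        assert abs(n_fatal - 100) <= 3 * sd

    def test_invalid_config_raises(self):
        cfg = syn.SimulationConfig()
        cfg.fires.n_fires = 0
        with pytest.raises(ValueError):
            syn.generate_truth(cfg, seed=1)
        cfg = syn.SimulationConfig()
        cfg.world.width_km = 0
        with pytest.raises(ValueError):
            syn.generate_truth(cfg, seed=1)


class TestRenderSources:
    def test_ics209_era_fatality_missingness(self, sim_config, small_world):
        world, fires = small_world
        table = syn.render_sources(fires, "ics209", sim_config.noise, 7, sim_config, world)
        years = pd.to_datetime(table.ignition_date).dt.year
        early = table[years <= 2013]
        late = table[years >= 2014]
        assert early.civilian_fatalities.isna().all()
        assert early.total_fatalities.notna().all()
        assert late.civilian_fatalities.notna().all()

    def test_redbooks_combined_era_and_state(self, sim_config, small_world):
        world, fires = small_world
        table = syn.render_sources(fires, "redbooks", sim_config.noise, 7, sim_config, world)
        assert "state" not in table.columns  # all rows implicitly California-like
        era = table[(table.year >= 2007) & (table.year <= 2009)]
        other = table[(table.year < 2007) | (table.year > 2009)]
        assert era.combined_damaged_destroyed.notna().all()
        assert era.destroyed_structures.isna().all()
        assert other.combined_damaged_destroyed.isna().all()

    def test_redbooks_combined_is_sum(self):
        cfg = syn.SimulationConfig()
        cfg.fires.n_fires = 30
        cfg.fires.year_range = (2008, 2008)
        cfg.noise.p_name_edit = 0
        world, fires = syn.generate_truth(cfg, seed=5)
        table = syn.render_sources(fires, "redbooks", cfg.noise, 5, cfg, world)
        by_id = {f.truth_id: f for f in fires}
        assert len(table) > 0
        for row in table.itertuples():
            truth = by_id[row.truth_id]
            assert row.combined_damaged_destroyed == (
                truth.damaged_structures + truth.destroyed_structures
            )

    def test_redbooks_large_fire_threshold(self, sim_config, small_world):
        world, fires = small_world
        table = syn.render_sources(fires, "redbooks", sim_config.noise, 7, sim_config, world)
        included = set(table.truth_id)
        for fire in fires:
            assert (fire.truth_id in included) == fire.in_redbooks(sim_config)

    def test_fmag_schema_minimal(self, sim_config, small_world):
        world, fires = small_world
        table = syn.render_sources(fires, "fmag", sim_config.noise, 7, sim_config, world)
        assert list(table.columns) == syn.FMAG_COLUMNS
        assert "destroyed_structures" not in table.columns
        assert table.declaration_date.notna().all()
        assert set(table.truth_id) == {f.truth_id for f in fires if f.fmag}

    def test_zero_noise_names_identical(self, small_world):
        world, fires = small_world
        quiet = syn.NoiseConfig(p_name_edit=0.0, date_jitter_days=0, p_case_noise=0.0)
        table = syn.render_sources(fires, "ics209", quiet, 7, None, world)
        by_id = {f.truth_id: f for f in fires}
        for row in table.itertuples():
            assert row.incident_name == by_id[row.truth_id].rendered_name
            assert row.ignition_date == by_id[row.truth_id].ignition_date.isoformat()

    def test_unknown_flavor_raises(self, small_world):
        _, fires = small_world
        with pytest.raises(ValueError):
            syn.render_sources(fires, "geomac")

    def test_hidden_truth_id_everywhere(self, sim_config, small_world):
        world, fires = small_world
        for flavor in ("ics209", "redbooks", "fmag"):
            table = syn.render_sources(fires, flavor, sim_config.noise, 7, sim_config, world)
            assert table.truth_id.notna().all()


class TestRenderPerimeters:
    def test_mtbs_size_rule(self, sim_config, small_world):
        _, fires = small_world
        perims = syn.render_perimeters(fires, "mtbs", 7, sim_config)
        included = {p.truth_id for p in perims}
        for fire in fires:
            expected = fire.in_mtbs and fire.passes_mtbs_size(sim_config.mtbs_rule)
            assert (fire.truth_id in included) == expected

    def test_small_eastern_fire_excluded(self):
        cfg = syn.SimulationConfig()
        cfg.fires.n_fires = 5
        cfg.fires.area_clip_acres = (400.0, 400.0)
        cfg.fires.p_east = 1.0
        cfg.fires.p_mtbs = 1.0
        _, fires = syn.generate_truth(cfg, seed=2)
        assert all(f.east and f.area_acres == 400.0 for f in fires)
        assert syn.render_perimeters(fires, "mtbs", 2, cfg) == []

    def test_fired_has_no_name_or_id(self, sim_config, small_world):
        _, fires = small_world
        perims = syn.render_perimeters(fires, "fired", 7, sim_config)
        assert perims
        assert all(p.name is None and p.shared_id is None for p in perims)

    def test_nifc_year_only(self, sim_config, small_world):
        _, fires = small_world
        perims = syn.render_perimeters(fires, "nifc", 7, sim_config)
        assert perims
        assert all(p.ignition_date is None and p.year is not None for p in perims)

    def test_unknown_flavor_raises(self, small_world):
        _, fires = small_world
        with pytest.raises(ValueError):
            syn.render_perimeters(fires, "geomac")


class TestPopulationGrid:
    def test_zero_towns_all_zero(self, sim_config):
        world = syn.generate_world(sim_config, seed=7)
        world.towns = []
        grid = syn.generate_population_grid(world, 2010)
        assert not grid.values.any()

    def test_peak_at_town_center(self, sim_config):
        world = syn.generate_world(sim_config, seed=7)
        town = world.towns[0]
        world.towns = [town]
        grid = syn.generate_population_grid(world, 2010)
        row, col = grid.index_of(town.x, town.y)
        assert grid.values[row, col] == grid.values.max() > 0

    def test_epoch_must_be_multiple_of_five(self, sim_config):
        world = syn.generate_world(sim_config, seed=7)
        with pytest.raises(ValueError):
            syn.generate_population_grid(world, 2012)

    def test_deterministic(self, sim_config):
        world = syn.generate_world(sim_config, seed=7)
        g1 = syn.generate_population_grid(world, 2015)
        g2 = syn.generate_population_grid(world, 2015)
        assert np.array_equal(g1.values, g2.values)

    def test_nonnegative_integers(self, sim_config):
        world = syn.generate_world(sim_config, seed=7)
        grid = syn.generate_population_grid(world, 2020)
        assert (grid.values >= 0).all()
        assert np.array_equal(grid.values, np.floor(grid.values))


def _grid(values, cell=100.0):
    return Grid(np.asarray(values, dtype=float), 0.0, 0.0, cell)


class TestClassifyWui:
    def test_intermix(self):
        layer = syn.classify_wui(_grid([[10.0]]), _grid([[0.6]]))
        assert layer.classes.values[0, 0] == 1

    def test_low_housing_is_non_wui(self):
        layer = syn.classify_wui(_grid([[5.0]]), _grid([[0.6]]))
        assert layer.classes.values[0, 0] == 0

    def test_interface_near_large_patch(self):
        # 60x60 cells at 100 m; a 6 km^2 patch of 0.8 vegetation on the left,
        # a housed low-vegetation cell 1 km to its right -> interface
        veg = np.full((60, 60), 0.3)
        veg[:30, :20] = 0.8  # 30*20 cells = 6 km^2
        housing = np.zeros((60, 60))
        housing[15, 29] = 10.0  # 1 km from the patch edge (column 19)
        layer = syn.classify_wui(_grid(housing), _grid(veg))
        assert layer.classes.values[15, 29] == 2

    def test_far_from_patch_is_non_wui(self):
        veg = np.full((60, 60), 0.3)
        veg[:30, :20] = 0.8
        housing = np.zeros((60, 60))
        housing[15, 50] = 10.0  # 3.1 km from the patch: beyond 2.4 km
        layer = syn.classify_wui(_grid(housing), _grid(veg))
        assert layer.classes.values[15, 50] == 0

    def test_small_patch_does_not_qualify(self):
        veg = np.full((60, 60), 0.3)
        veg[:10, :10] = 0.8  # 1 km^2 < 5 km^2
        housing = np.zeros((60, 60))
        housing[5, 15] = 10.0
        layer = syn.classify_wui(_grid(housing), _grid(veg))
        assert layer.classes.values[5, 15] == 0

    def test_frame_mismatch_raises(self):
        with pytest.raises(ValueError):
            syn.classify_wui(_grid([[1.0]]), _grid([[0.5, 0.5]]))

    def test_exactly_one_class_per_cell_and_idempotent(self, sim_config):
        world = syn.generate_world(sim_config, seed=7)
        layer = syn.classify_wui(world.housing, world.vegetation)
        assert set(np.unique(layer.classes.values)) <= {0, 1, 2}
        again = syn.classify_wui(layer.housing, layer.vegetation, layer.rules)
        assert np.array_equal(layer.classes.values, again.classes.values)


class TestIntendedOutcomes:
    def test_groups_cover_visible_fires(self, sim_config, small_world):
        _, fires = small_world
        outcomes = syn.intended_outcomes(fires, sim_config)
        partition = syn.truth_partition(fires)
        visible_groups = {
            partition[f.truth_id]
            for f in fires
            if f.in_ics209 or f.in_redbooks(sim_config) or f.fmag
        }
        assert set(outcomes) == visible_groups

    def test_complex_members_share_group(self, small_world):
        _, fires = small_world
        partition = syn.truth_partition(fires)
        for fire in fires:
            if fire.complex_id:
                assert partition[fire.truth_id] == fire.complex_id
                assert fire.complex_name
                assert standardize_name(fire.complex_name) == fire.complex_name
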