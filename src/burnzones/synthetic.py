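"""Reproducible synthetic fire world and source-flavored renderings.

Generates a planar world (counties, towns, vegetation/housing grids) and a
registry of ground-truth fires, then renders them into noisy tables and
perimeter sets that emulate the schema quirks of the real sources:

* incident-summary flavor (``ics209``): civilian fatalities missing for
  ignition years 2000-2013 (total fatalities only), origin coordinates and
  burn area, sometimes a shared interagency ID;
* California annual-report flavor (``redbooks``): only large fires in the
  configured state, a single combined damaged/destroyed count for 2007-2009,
  no state column, no coordinates;
* federal-assistance flavor (``fmag``): identifying fields and a
  declaration date only;
* perimeter flavors: ``mtbs`` (regional size cutoffs, names, dates),
  ``fired`` (geometry and dates, no names or IDs), ``nifc`` (names and
  ignition year only).

Every rendered row carries a hidden ``truth_id`` used only by tests.

Fires are generated in two community regimes — "near" (origin within a few
kilometres of a town) and "far" (tens of kilometres from every town) — so
the intended community flag of every fire is unambiguous under any geometry
the pipeline may assign.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Polygon, box

from .frames import LocalFrame, acres_to_m2
from .grids import Grid
from .linkage import jw_distance
from .records import PerimeterRecord
from .standardize import Gazetteer, standardize_name

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class WorldConfig:
    width_km: float = 200.0
    height_km: float = 200.0
    cell_size_m: float = 100.0
    state_names: tuple[str, ...] = ("CA", "NV")
    counties_per_state: int = 4
    n_towns: int = 10
    town_margin_km: float = 50.0
    town_peak_range: tuple[float, float] = (40.0, 150.0)  # people per cell
    town_sigma_range_m: tuple[float, float] = (800.0, 3500.0)
    town_growth_rate: float = 0.01  # linear per-year growth from 2000
    lon0: float = -120.0
    lat0: float = 39.0


@dataclass
class FireConfig:
    n_fires: int = 200
    year_range: tuple[int, int] = (2000, 2025)
    area_log_mean: float = 5.8  # log-acres
    area_log_sigma: float = 1.4
    area_clip_acres: tuple[float, float] = (10.0, 20_000.0)
    p_civilian_fatality: float = 0.05
    civilian_fatality_mean: float = 1.5
    p_responder_fatality: float = 0.04
    responder_fatality_mean: float = 1.0
    p_destroyed: float = 0.45
    destroyed_mean: float = 8.0
    p_damaged: float = 0.30
    damaged_mean: float = 4.0
    p_fmag: float = 0.15
    complex_fraction: float = 0.10
    near_town_fraction: float = 0.70
    near_town_max_km: float = 3.0
    far_town_min_km: float = 40.0
    p_ics209: float = 0.95
    p_origin: float = 0.97
    p_area: float = 0.95
    p_shared_id: float = 0.50
    p_mtbs: float = 0.90
    p_fired: float = 0.60
    p_nifc: float = 0.70
    p_east: float = 0.30
    # fires closer in time than the matching windows are kept spatially
    # apart so origin-based perimeter matching cannot cross-link them
    min_fire_separation_km: float = 12.0
    separation_window_days: int = 45


@dataclass
class NoiseConfig:
    p_name_edit: float = 0.15
    max_name_edits: int = 1
    date_jitter_days: int = 5
    p_case_noise: float = 0.5


@dataclass
class RedbooksRule:
    """Large-fire inclusion rule, simplified to per-era acreage thresholds.

    The pre-2008 multi-criterion rule is reduced to a single threshold plus
    an optional destroyed-structure clause; the dollar-damage clause is off
    by default.
    """

    pre2008_min_acres: float = 300.0
    post2008_min_acres: float = 300.0
    min_destroyed: Optional[int] = 3  # pre-2008 structural clause
    damage_dollars_clause: bool = False


@dataclass
class MtbsRule:
    west_min_acres: float = 1000.0
    east_min_acres: float = 500.0


@dataclass
class SimulationConfig:
    world: WorldConfig = field(default_factory=WorldConfig)
    fires: FireConfig = field(default_factory=FireConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    redbooks_rule: RedbooksRule = field(default_factory=RedbooksRule)
    mtbs_rule: MtbsRule = field(default_factory=MtbsRule)
    redbooks_state: str = "CA"
    min_name_separation: float = 0.34

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)


# ---------------------------------------------------------------------------
# world types
# ---------------------------------------------------------------------------


@dataclass
class County:
    state: str
    name: str
    polygon: Polygon


@dataclass
class Town:
    x: float
    y: float
    peak: float  # people per cell at the centre (epoch 2000)
    sigma_m: float


@dataclass
class SyntheticWorld:
    frame: LocalFrame
    width_m: float
    height_m: float
    cell_size_m: float
    counties: list[County]
    towns: list[Town]
    vegetation: Grid  # fraction in [0, 1]
    housing: Grid  # houses per km^2
    seed: int
    config: SimulationConfig

    def gazetteer(self) -> Gazetteer:
        by_state: dict[str, dict[str, Polygon]] = {}
        for county in self.counties:
            by_state.setdefault(county.state, {})[county.name] = county.polygon
        return Gazetteer(counties=by_state)

    def empty_grid(self) -> Grid:
        nrows = int(round(self.height_m / self.cell_size_m))
        ncols = int(round(self.width_m / self.cell_size_m))
        return Grid(np.zeros((nrows, ncols)), 0.0, 0.0, self.cell_size_m)


@dataclass
class TruthFire:
    truth_id: str
    name: str
    complex_id: Optional[str]
    complex_name: Optional[str]
    state: str
    counties: tuple[tuple[str, str], ...]
    origin: tuple[float, float]
    perimeter: Polygon
    area_acres: float
    ignition_date: dt.date
    containment_date: dt.date
    civilian_fatalities: int
    responder_fatalities: int
    destroyed_structures: int
    damaged_structures: int
    fmag: bool
    east: bool
    near_community: bool
    in_ics209: bool
    has_origin: bool
    has_area: bool
    shared_id: Optional[str]
    in_mtbs: bool
    in_fired: bool
    in_nifc: bool

    @property
    def total_fatalities(self) -> int:
        return self.civilian_fatalities + self.responder_fatalities

    @property
    def rendered_name(self) -> str:
        return self.complex_name or self.name

    def in_redbooks(self, cfg: SimulationConfig) -> bool:
        if self.state != cfg.redbooks_state:
            return False
        rule = cfg.redbooks_rule
        year = self.ignition_date.year
        if year >= 2008:
            return self.area_acres >= rule.post2008_min_acres
        if self.area_acres >= rule.pre2008_min_acres:
            return True
        return (
            rule.min_destroyed is not None
            and self.destroyed_structures >= rule.min_destroyed
        )

    def passes_mtbs_size(self, rule: MtbsRule) -> bool:
        cutoff = rule.east_min_acres if self.east else rule.west_min_acres
        return self.area_acres >= cutoff


# ---------------------------------------------------------------------------
# name sampling
# ---------------------------------------------------------------------------

_NAME_WORDS = (
    "ALDER ANTELOPE ARROW ASPEN BADGER BASIN BEAR BEAVER BIRCH BISON BITTER "
    "BLUE BOBCAT BOULDER BRISTLE BUCK BUTTE CACTUS CARIBOU CEDAR CHALK "
    "CHERRY CINDER CLOVER COBALT CONDOR COPPER COTTON COUGAR COYOTE CRANE "
    "CRYSTAL CYPRESS DEER DOVE DRIFT EAGLE ELDER ELK EMBER ERMINE FALCON "
    "FAWN FERN FINCH FLINT FOX GARNET GOOSE GRANITE HARRIER HAWK HAZEL "
    "HERON HICKORY HONEY IBEX INDIGO IRON JADE JASPER JUNIPER KESTREL "
    "LANTERN LARCH LARK LILAC LINDEN LYNX MAGPIE MALLARD MAPLE MARTEN "
    "MESQUITE MINK MOOSE MOSS MUSTANG NUTMEG OAK OCELOT ONYX OSPREY OTTER "
    "OWL PEBBLE PELICAN PINTO PLOVER POPLAR PUMA QUAIL QUARTZ RACCOON RAVEN "
    "ROWAN SABLE SAGE SALMON SHALE SIERRA SPARROW SPRUCE STAG STORK SUMAC "
    "SWAN TALON TEAL THISTLE TOPAZ TROUT TULIP UMBER VIREO WALNUT WEASEL "
    "WILLOW WOLF WREN ZINNIA"
).split()


def _sample_name(
    rng: np.random.Generator, conflict_names: list[str], min_separation: float
) -> str:
    """Sample a two-word name whose standardized form is at least
    ``min_separation`` from every name it could be confused with.

    Global pairwise separation is infeasible under Jaro-Winkler (random
    word pairs are too alike), so separation is enforced only against the
    supplied conflict set — fires close enough in time that the matching
    rules could ever compare them.
    """
    # dense worlds exhaust two-word names at full separation: fall back to
    # three-word names, then progressively relax (still above the 0.25 match
    # cap so distinct fires can never pair under the default rules)
    thresholds = (min_separation, max(0.28, min_separation - 0.03), 0.28)
    for threshold in thresholds:
        for n_words in (2, 3):
            for _ in range(2000):
                idx = rng.choice(len(_NAME_WORDS), size=n_words, replace=False)
                candidate = " ".join(_NAME_WORDS[i] for i in idx)
                std = standardize_name(candidate)
                if all(
                    jw_distance(std, other) >= threshold
                    for other in conflict_names
                ):
                    return candidate
    raise RuntimeError("could not sample a sufficiently distinct name")


# ---------------------------------------------------------------------------
# world generation
# ---------------------------------------------------------------------------

_COUNTY_NAMES = {
    "CA": ("LOS ANGELES", "KERN", "FRESNO", "SHASTA", "MONO", "INYO"),
    "NV": ("CLARK", "WASHOE", "ELKO", "NYE", "LANDER", "EUREKA"),
}
_FALLBACK_COUNTIES = (
    "ADAMS", "BAXTER", "CALDWELL", "DAWSON", "EMERY", "FALLON", "GRANGER",
    "HOLT", "IRVING", "JUDITH",
)


def _county_names(state: str, n: int) -> list[str]:
    pool = _COUNTY_NAMES.get(state, _FALLBACK_COUNTIES)
    if n <= len(pool):
        return list(pool[:n])
    names = list(pool)
    i = 0
    while len(names) < n:
        names.append(f"{_FALLBACK_COUNTIES[i % len(_FALLBACK_COUNTIES)]} {len(names)}")
        i += 1
    return names


def _build_counties(cfg: WorldConfig, width_m: float, height_m: float) -> list[County]:
    counties = []
    band_w = width_m / len(cfg.state_names)
    slice_h = height_m / cfg.counties_per_state
    for si, state in enumerate(cfg.state_names):
        names = _county_names(state, cfg.counties_per_state)
        for ci in range(cfg.counties_per_state):
            counties.append(
                County(
                    state=state,
                    name=names[ci],
                    polygon=box(
                        si * band_w,
                        ci * slice_h,
                        (si + 1) * band_w,
                        (ci + 1) * slice_h,
                    ),
                )
            )
    return counties


def _build_vegetation(
    rng: np.random.Generator, nrows: int, ncols: int, cell_size: float
) -> np.ndarray:
    block = max(1, int(4000 / cell_size))  # ~4-km blocks
    coarse = rng.random((nrows // block + 2, ncols // block + 2))
    fine = np.kron(coarse, np.ones((block, block)))[:nrows, :ncols]
    fine = ndimage.gaussian_filter(fine, sigma=block / 2)
    lo, hi = fine.min(), fine.max()
    return 0.05 + 0.9 * (fine - lo) / max(hi - lo, 1e-9)


def _town_field(
    towns: Sequence[Town], grid: Grid, scale: float = 1.0
) -> np.ndarray:
    """Sum of Gaussian town kernels evaluated at cell centres."""
    values = np.zeros((grid.nrows, grid.ncols))
    xs, ys = grid.cell_centers()
    for town in towns:
        reach = 4.0 * town.sigma_m
        cmask = np.abs(xs - town.x) <= reach
        rmask = np.abs(ys - town.y) <= reach
        if not cmask.any() or not rmask.any():
            continue
        dx = xs[cmask] - town.x
        dy = ys[rmask] - town.y
        kernel = np.exp(
            -(dy[:, None] ** 2 + dx[None, :] ** 2) / (2 * town.sigma_m**2)
        )
        values[np.ix_(rmask, cmask)] += scale * town.peak * kernel
    return values


def generate_world(cfg: SimulationConfig, seed: int) -> SyntheticWorld:
    wc = cfg.world
    width_m = wc.width_km * 1000.0
    height_m = wc.height_km * 1000.0
    if width_m <= 0 or height_m <= 0:
        raise ValueError("empty world extent")
    rng = np.random.default_rng([seed, 0])

    counties = _build_counties(wc, width_m, height_m)

    margin = wc.town_margin_km * 1000.0
    towns = []
    for _ in range(wc.n_towns):
        towns.append(
            Town(
                x=rng.uniform(margin, width_m - margin),
                y=rng.uniform(margin, height_m - margin),
                peak=rng.uniform(*wc.town_peak_range),
                sigma_m=rng.uniform(*wc.town_sigma_range_m),
            )
        )

    nrows = int(round(height_m / wc.cell_size_m))
    ncols = int(round(width_m / wc.cell_size_m))
    veg = Grid(
        _build_vegetation(rng, nrows, ncols, wc.cell_size_m),
        0.0,
        0.0,
        wc.cell_size_m,
    )
    base = Grid(np.zeros((nrows, ncols)), 0.0, 0.0, wc.cell_size_m)
    # houses/km^2: people-per-cell * 100 -> people/km^2, / 2.5 people per house
    housing = base.like(_town_field(towns, base) * 100.0 / 2.5)

    return SyntheticWorld(
        frame=LocalFrame(wc.lon0, wc.lat0),
        width_m=width_m,
        height_m=height_m,
        cell_size_m=wc.cell_size_m,
        counties=counties,
        towns=towns,
        vegetation=veg,
        housing=housing,
        seed=seed,
        config=cfg,
    )


def generate_population_grid(world: SyntheticWorld, epoch_year: int) -> Grid:
    """Population per 100-m cell for one 5-year epoch (floored to ints)."""
    if epoch_year % 5 != 0:
        raise ValueError(f"epoch year {epoch_year} is not a multiple of 5")
    growth = 1.0 + world.config.world.town_growth_rate * (epoch_year - 2000)
    base = world.empty_grid()
    field_values = _town_field(world.towns, base, scale=max(growth, 0.0))
    return base.like(np.floor(field_values))


# ---------------------------------------------------------------------------
# WUI classification
# ---------------------------------------------------------------------------


@dataclass
class WUIRuleConfig:
    veg_threshold: float = 0.5
    housing_min: float = 6.17
    interface_dist_m: float = 2400.0
    patch_min_area_km2: float = 5.0
    patch_veg_fraction: float = 0.75

    def __post_init__(self) -> None:
        if not (0 < self.veg_threshold < 1 and 0 < self.patch_veg_fraction < 1):
            raise ValueError("vegetation fractions must be in (0, 1)")
        if min(self.housing_min, self.interface_dist_m, self.patch_min_area_km2) <= 0:
            raise ValueError("WUI thresholds must be strictly positive")


@dataclass
class WUILayer:
    classes: Grid  # 0 = non-WUI, 1 = intermix, 2 = interface
    housing: Grid
    vegetation: Grid
    rules: WUIRuleConfig


def classify_wui(
    housing: Grid, vegetation: Grid, rules: Optional[WUIRuleConfig] = None
) -> WUILayer:
    """Classify each cell as intermix, interface, or non-WUI.

    Intermix: vegetation above the threshold and housing at or above the
    minimum. Interface: housing at or above the minimum, vegetation at or
    below the threshold, and the cell within the interface distance of an
    8-connected patch of highly vegetated cells of sufficient area.
    """
    rules = rules or WUIRuleConfig()
    if not housing.same_frame(vegetation):
        raise ValueError("housing and vegetation grids must share a frame")
    veg = vegetation.values
    houses = housing.values
    cell_size = housing.cell_size

    intermix = (veg > rules.veg_threshold) & (houses >= rules.housing_min)

    patch_cells = veg >= rules.patch_veg_fraction
    labels, n_labels = ndimage.label(patch_cells, structure=np.ones((3, 3)))
    qualifying = np.zeros_like(patch_cells)
    if n_labels:
        cell_area_km2 = (cell_size / 1000.0) ** 2
        sizes = ndimage.sum_labels(
            np.ones_like(labels), labels, index=np.arange(1, n_labels + 1)
        )
        big = np.flatnonzero(sizes * cell_area_km2 >= rules.patch_min_area_km2) + 1
        qualifying = np.isin(labels, big)
    if qualifying.any():
        dist = ndimage.distance_transform_edt(
            ~qualifying, sampling=cell_size
        )
        near_patch = dist <= rules.interface_dist_m
    else:
        near_patch = np.zeros_like(patch_cells)

    interface = (
        (houses >= rules.housing_min)
        & (veg <= rules.veg_threshold)
        & near_patch
        & ~intermix
    )

    classes = np.zeros(veg.shape, dtype=int)
    classes[intermix] = 1
    classes[interface] = 2
    return WUILayer(
        classes=housing.like(classes),
        housing=housing,
        vegetation=vegetation,
        rules=rules,
    )


# ---------------------------------------------------------------------------
# truth fires
# ---------------------------------------------------------------------------


def _wobbly_circle(
    rng: np.random.Generator,
    center: tuple[float, float],
    area_m2: float,
    n_vertices: int = 64,
) -> Polygon:
    """Simple star-shaped polygon around the centre with exact planar area."""
    angles = np.linspace(0, 2 * math.pi, n_vertices, endpoint=False)
    wobble = 1.0 + 0.25 * np.sin(angles * rng.integers(2, 5)) * rng.uniform(0.3, 1.0)
    radius = math.sqrt(area_m2 / math.pi)
    xs = center[0] + radius * wobble * np.cos(angles)
    ys = center[1] + radius * wobble * np.sin(angles)
    poly = Polygon(zip(xs, ys))
    scale = math.sqrt(area_m2 / poly.area)
    xs = center[0] + (xs - center[0]) * scale
    ys = center[1] + (ys - center[1]) * scale
    return Polygon(zip(xs, ys))


def _sample_origin(
    rng: np.random.Generator, world: SyntheticWorld, near: bool, fire_cfg: FireConfig
) -> tuple[float, float]:
    towns = world.towns
    pad = 16_000.0  # keep perimeters inside the extent
    if near and towns:
        for _ in range(1000):
            town = towns[rng.integers(len(towns))]
            angle = rng.uniform(0, 2 * math.pi)
            dist = rng.uniform(0, fire_cfg.near_town_max_km * 1000.0)
            x = town.x + dist * math.cos(angle)
            y = town.y + dist * math.sin(angle)
            if pad <= x <= world.width_m - pad and pad <= y <= world.height_m - pad:
                return (x, y)
        raise RuntimeError("could not place a near-town fire inside the extent")
    min_d = fire_cfg.far_town_min_km * 1000.0
    for _ in range(10_000):
        x = rng.uniform(pad, world.width_m - pad)
        y = rng.uniform(pad, world.height_m - pad)
        if all(math.hypot(x - t.x, y - t.y) >= min_d for t in towns):
            return (x, y)
    raise RuntimeError("could not place a far-from-town fire; extent too small")


def _fire_counties(
    world: SyntheticWorld, origin: tuple[float, float], perimeter: Polygon
) -> tuple[str, tuple[tuple[str, str], ...]]:
    origin_state = None
    pairs = []
    from shapely.geometry import Point

    pt = Point(origin)
    for county in world.counties:
        if county.polygon.intersects(perimeter):
            pairs.append((county.state, county.name))
        if origin_state is None and county.polygon.covers(pt):
            origin_state = county.state
    if origin_state is None:
        raise RuntimeError("fire origin outside every county")
    return origin_state, tuple(sorted(set(pairs)))


def _sample_count(rng, p: float, mean: float) -> int:
    if rng.random() >= p:
        return 0
    return 1 + int(rng.poisson(mean))


def generate_truth(
    cfg: Optional[SimulationConfig] = None, seed: int = 0
) -> tuple[SyntheticWorld, list[TruthFire]]:
    """Generate the world and the ground-truth fire registry.

    Deterministic for a fixed (config, seed). Every fire origin lies inside
    its listed counties and every perimeter's planar area matches the
    registered ``area_acres`` within 1%.
    """
    cfg = cfg or SimulationConfig()
    fc = cfg.fires
    if fc.n_fires <= 0:
        raise ValueError("n_fires must be positive")
    y0, y1 = fc.year_range
    if not (2000 <= y0 <= y1 <= 2025):
        raise ValueError("year_range must lie within 2000-2025")

    world = generate_world(cfg, seed)
    rng = np.random.default_rng([seed, 1])

    fires: list[TruthFire] = []
    for i in range(fc.n_fires):
        near = bool(rng.random() < fc.near_town_fraction)
        area_acres = float(
            np.clip(
                rng.lognormal(fc.area_log_mean, fc.area_log_sigma),
                *fc.area_clip_acres,
            )
        )
        for _ in range(500):
            year = int(rng.integers(y0, y1 + 1))
            # dates stay away from year boundaries so jitter cannot flip the year
            day_of_year = int(rng.integers(30, 331))
            ignition = dt.date(year, 1, 1) + dt.timedelta(days=day_of_year - 1)
            origin = _sample_origin(rng, world, near, fc)
            if _separated(origin, ignition, fires, fc):
                break
        else:
            raise RuntimeError("could not place fires with required separation")
        perimeter = _wobbly_circle(rng, origin, acres_to_m2(area_acres))
        state, counties = _fire_counties(world, origin, perimeter)
        containment = ignition + dt.timedelta(days=int(rng.integers(1, 60)))

        in_ics = bool(rng.random() < fc.p_ics209)
        fires.append(
            TruthFire(
                truth_id=f"T{i:05d}",
                name="",  # assigned after complex grouping
                complex_id=None,
                complex_name=None,
                state=state,
                counties=counties,
                origin=origin,
                perimeter=perimeter,
                area_acres=area_acres,
                ignition_date=ignition,
                containment_date=containment,
                civilian_fatalities=_sample_count(
                    rng, fc.p_civilian_fatality, fc.civilian_fatality_mean
                ),
                responder_fatalities=_sample_count(
                    rng, fc.p_responder_fatality, fc.responder_fatality_mean
                ),
                destroyed_structures=_sample_count(
                    rng, fc.p_destroyed, fc.destroyed_mean
                ),
                damaged_structures=_sample_count(
                    rng, fc.p_damaged, fc.damaged_mean
                ),
                fmag=bool(rng.random() < fc.p_fmag),
                east=bool(rng.random() < fc.p_east),
                near_community=near,
                in_ics209=in_ics,
                has_origin=in_ics and bool(rng.random() < fc.p_origin),
                has_area=in_ics and bool(rng.random() < fc.p_area),
                shared_id=(
                    f"IRW-{i:06d}"
                    if in_ics and rng.random() < fc.p_shared_id
                    else None
                ),
                in_mtbs=bool(rng.random() < fc.p_mtbs),
                in_fired=bool(rng.random() < fc.p_fired),
                in_nifc=bool(rng.random() < fc.p_nifc),
            )
        )

    _force_complexes(rng, world, fires, cfg)
    _assign_names(rng, fires, cfg)
    return world, fires


def _separated(
    origin: tuple[float, float],
    ignition: dt.date,
    fires: Sequence[TruthFire],
    fc: FireConfig,
) -> bool:
    min_m = fc.min_fire_separation_km * 1000.0
    for fire in fires:
        if abs((ignition - fire.ignition_date).days) <= fc.separation_window_days:
            if math.hypot(
                origin[0] - fire.origin[0], origin[1] - fire.origin[1]
            ) < min_m:
                return False
    return True


def _force_complexes(
    rng: np.random.Generator,
    world: SyntheticWorld,
    fires: list[TruthFire],
    cfg: SimulationConfig,
) -> None:
    """Pair up fires into administrative complexes (in place).

    The partner fire is relocated next to the base fire and re-dated within
    a few days so members share counties and a tight date window; both
    members are rendered under the shared complex name."""
    fc = cfg.fires
    n_complexes = int(round(fc.complex_fraction * fc.n_fires / 2))
    free = list(range(len(fires)))
    for ci in range(n_complexes):
        if len(free) < 2:
            break
        base_i = free.pop(int(rng.integers(len(free))))
        partner_i = free.pop(int(rng.integers(len(free))))
        base = fires[base_i]
        partner = fires[partner_i]
        base.complex_id = partner.complex_id = f"CX{ci:03d}"

        angle = rng.uniform(0, 2 * math.pi)
        dist = rng.uniform(500.0, 2000.0)
        origin = (
            base.origin[0] + dist * math.cos(angle),
            base.origin[1] + dist * math.sin(angle),
        )
        perimeter = _wobbly_circle(rng, origin, acres_to_m2(partner.area_acres))
        state, counties = _fire_counties(world, origin, perimeter)
        ignition = base.ignition_date + dt.timedelta(days=int(rng.integers(-5, 6)))
        partner.origin = origin
        partner.perimeter = perimeter
        partner.state = state
        partner.counties = counties
        partner.ignition_date = ignition
        partner.containment_date = ignition + dt.timedelta(
            days=int(rng.integers(1, 60))
        )
        partner.near_community = base.near_community


def _assign_names(
    rng: np.random.Generator, fires: list[TruthFire], cfg: SimulationConfig
) -> None:
    """Assign names per truth group, distinct within temporal neighborhoods.

    Two groups whose ignition years are within one year of each other get
    names at least ``min_name_separation`` apart, so no matching rule
    (30-day windows, or the ignition-year window of the year-only perimeter
    flavor) can ever confuse them."""
    groups: dict[str, list[TruthFire]] = {}
    for fire in fires:
        groups.setdefault(fire.complex_id or fire.truth_id, []).append(fire)
    assigned: list[tuple[set[int], str]] = []
    for gid in sorted(groups, key=lambda g: groups[g][0].truth_id):
        members = groups[gid]
        years = {m.ignition_date.year for m in members}
        conflicts = [
            std
            for other_years, std in assigned
            if any(abs(y - oy) <= 1 for y in years for oy in other_years)
        ]
        name = _sample_name(rng, conflicts, cfg.min_name_separation)
        assigned.append((years, standardize_name(name)))
        if len(members) == 1:
            members[0].name = name
        else:
            for k, member in enumerate(members, start=1):
                member.name = f"{name} {k}"
                member.complex_name = name


def truth_partition(fires: Sequence[TruthFire]) -> dict[str, str]:
    """truth_id -> group id (complex id, or own id for singleton fires)."""
    return {f.truth_id: (f.complex_id or f.truth_id) for f in fires}


# ---------------------------------------------------------------------------
# source rendering
# ---------------------------------------------------------------------------


def _perturb_name(rng: np.random.Generator, name: str, noise: NoiseConfig) -> str:
    """Bounded, reproducible name noise.

    Case/punctuation noise is removed entirely by standardization; character
    edits are restricted to the last word so name prefixes (and hence the
    Jaro-Winkler prefix boost) stay stable.
    """
    out = name
    if noise.p_case_noise and rng.random() < noise.p_case_noise:
        out = out.title()
    if noise.p_name_edit and rng.random() < noise.p_name_edit:
        for _ in range(noise.max_name_edits):
            last_space = out.rfind(" ")
            lo = max(last_space + 2, len(out) - 4)
            if lo >= len(out):
                continue
            pos = int(rng.integers(lo, len(out)))
            if rng.random() < 0.5 and len(out) > pos + 1:
                out = out[:pos] + out[pos + 1 :]  # deletion
            else:
                letter = chr(ord("A") + int(rng.integers(26)))
                out = out[:pos] + letter + out[pos + 1 :]
    return out


def _jitter_date(
    rng: np.random.Generator, date: dt.date, noise: NoiseConfig
) -> dt.date:
    if noise.date_jitter_days <= 0:
        return date
    return date + dt.timedelta(
        days=int(rng.integers(-noise.date_jitter_days, noise.date_jitter_days + 1))
    )


def _county_names_for(fire: TruthFire, state: str) -> str:
    return ", ".join(c for s, c in fire.counties if s == state)


ICS209_COLUMNS = [
    "source_id", "incident_name", "state", "county", "ignition_date",
    "containment_date", "civilian_fatalities", "total_fatalities",
    "destroyed_structures", "damaged_structures", "threatened_structures",
    "injuries", "evacuated", "estimated_cost", "origin_lon", "origin_lat",
    "area_acres", "shared_id", "truth_id",
]
REDBOOKS_COLUMNS = [
    "source_id", "fire_name", "county", "year", "ignition_date",
    "containment_date", "civilian_fatalities", "total_fatalities",
    "destroyed_structures", "damaged_structures",
    "combined_damaged_destroyed", "area_acres", "truth_id",
]
FMAG_COLUMNS = [
    "declaration_id", "incident_name", "state", "county", "year",
    "ignition_date", "containment_date", "declaration_date", "truth_id",
]


def render_sources(
    truth: Sequence[TruthFire],
    flavor: str,
    noise: Optional[NoiseConfig] = None,
    seed: int = 0,
    cfg: Optional[SimulationConfig] = None,
    world: Optional[SyntheticWorld] = None,
) -> pd.DataFrame:
    """Render the truth registry into one noisy source-flavored table."""
    if flavor not in ("ics209", "redbooks", "fmag"):
        raise ValueError(f"unknown source flavor {flavor!r}")
    cfg = cfg or SimulationConfig()
    noise = noise or cfg.noise
    rng = np.random.default_rng([seed, {"ics209": 10, "redbooks": 11, "fmag": 12}[flavor]])
    frame = world.frame if world is not None else LocalFrame(
        cfg.world.lon0, cfg.world.lat0
    )

    rows = []
    for i, fire in enumerate(truth):
        year = fire.ignition_date.year
        name = _perturb_name(rng, fire.rendered_name, noise)
        ignition = _jitter_date(rng, fire.ignition_date, noise).isoformat()
        containment = _jitter_date(rng, fire.containment_date, noise)
        containment = max(containment, fire.ignition_date).isoformat()

        if flavor == "ics209":
            if not fire.in_ics209:
                continue
            lon = lat = None
            if fire.has_origin:
                lon, lat = frame.to_lonlat(*fire.origin)
            rows.append(
                {
                    "source_id": f"ICS-{i:05d}",
                    "incident_name": name,
                    "state": fire.state,
                    "county": _county_names_for(fire, fire.state),
                    "ignition_date": ignition,
                    "containment_date": containment,
                    # civilian breakdown only reported from 2014 onward
                    "civilian_fatalities": (
                        fire.civilian_fatalities if year >= 2014 else None
                    ),
                    "total_fatalities": fire.total_fatalities,
                    "destroyed_structures": fire.destroyed_structures,
                    "damaged_structures": fire.damaged_structures,
                    "threatened_structures": (
                        int(rng.integers(1, 500)) if rng.random() < 0.3 else None
                    ),
                    "injuries": int(rng.integers(1, 20)) if rng.random() < 0.1 else None,
                    "evacuated": int(rng.integers(10, 5000)) if rng.random() < 0.05 else None,
                    "estimated_cost": (
                        float(rng.integers(10, 5000) * 1000)
                        if rng.random() < 0.36
                        else None
                    ),
                    "origin_lon": lon,
                    "origin_lat": lat,
                    "area_acres": fire.area_acres if fire.has_area else None,
                    "shared_id": fire.shared_id,
                    "truth_id": fire.truth_id,
                }
            )
        elif flavor == "redbooks":
            if not fire.in_redbooks(cfg):
                continue
            era = 2007 <= year <= 2009
            origin_county = next(
                (c for s, c in fire.counties if s == fire.state),
                fire.counties[0][1] if fire.counties else "",
            )
            rows.append(
                {
                    "source_id": f"RB-{i:05d}",
                    "fire_name": name,
                    "county": origin_county,
                    "year": year,
                    "ignition_date": ignition,
                    "containment_date": containment,
                    "civilian_fatalities": fire.civilian_fatalities,
                    "total_fatalities": fire.total_fatalities,
                    "destroyed_structures": None if era else fire.destroyed_structures,
                    "damaged_structures": None if era else fire.damaged_structures,
                    "combined_damaged_destroyed": (
                        fire.damaged_structures + fire.destroyed_structures
                        if era
                        else None
                    ),
                    "area_acres": fire.area_acres,
                    "truth_id": fire.truth_id,
                }
            )
        else:  # fmag
            if not fire.fmag:
                continue
            declaration = fire.ignition_date + dt.timedelta(
                days=int(rng.integers(0, 6))
            )
            rows.append(
                {
                    "declaration_id": f"FM-{i:05d}",
                    "incident_name": name,
                    "state": fire.state,
                    "county": _county_names_for(fire, fire.state),
                    "year": year,
                    "ignition_date": ignition,
                    "containment_date": containment,
                    "declaration_date": declaration.isoformat(),
                    "truth_id": fire.truth_id,
                }
            )

    columns = {
        "ics209": ICS209_COLUMNS,
        "redbooks": REDBOOKS_COLUMNS,
        "fmag": FMAG_COLUMNS,
    }[flavor]
    return pd.DataFrame(rows, columns=columns)


def render_perimeters(
    truth: Sequence[TruthFire],
    flavor: str,
    seed: int = 0,
    cfg: Optional[SimulationConfig] = None,
) -> list[PerimeterRecord]:
    """Render the truth registry into one perimeter flavor."""
    if flavor not in ("mtbs", "fired", "nifc"):
        raise ValueError(f"unknown perimeter flavor {flavor!r}")
    cfg = cfg or SimulationConfig()
    records = []
    for i, fire in enumerate(truth):
        if flavor == "mtbs":
            if not (fire.in_mtbs and fire.passes_mtbs_size(cfg.mtbs_rule)):
                continue
            records.append(
                PerimeterRecord(
                    flavor="mtbs",
                    perimeter_id=f"MTBS-{i:05d}",
                    geometry=fire.perimeter,
                    area_acres=fire.area_acres,
                    name=standardize_name(fire.rendered_name),
                    shared_id=fire.shared_id,
                    ignition_date=fire.ignition_date,
                    truth_id=fire.truth_id,
                )
            )
        elif flavor == "fired":
            if not fire.in_fired:
                continue
            records.append(
                PerimeterRecord(
                    flavor="fired",
                    perimeter_id=f"FIRED-{i:05d}",
                    geometry=fire.perimeter,
                    area_acres=fire.area_acres,
                    ignition_date=fire.ignition_date,
                    containment_date=fire.containment_date,
                    truth_id=fire.truth_id,
                )
            )
        else:  # nifc: names and shared IDs, ignition *year* only
            if not fire.in_nifc:
                continue
            records.append(
                PerimeterRecord(
                    flavor="nifc",
                    perimeter_id=f"NIFC-{i:05d}",
                    geometry=fire.perimeter,
                    area_acres=fire.area_acres,
                    name=standardize_name(fire.rendered_name),
                    shared_id=fire.shared_id,
                    year=fire.ignition_date.year,
                    truth_id=fire.truth_id,
                )
            )
    return records


# ---------------------------------------------------------------------------
# intended outcomes (generator ground truth for end-to-end tests)
# ---------------------------------------------------------------------------


@dataclass
class IntendedOutcome:
    group_id: str
    truth_ids: tuple[str, ...]
    fatality_met: bool
    structure_met: bool
    fmag_met: bool
    community_flag: Optional[bool]

    @property
    def any_met(self) -> bool:
        return self.fatality_met or self.structure_met or self.fmag_met

    @property
    def flagged(self) -> bool:
        return self.any_met and self.community_flag is True


def intended_outcomes(
    fires: Sequence[TruthFire], cfg: Optional[SimulationConfig] = None
) -> dict[str, IntendedOutcome]:
    """Expected post-pipeline outcome per truth group.

    Mirrors the availability and precedence semantics of the sources: the
    annual-report flavor wins on counts when present, the incident-summary
    flavor reports no civilian breakdown before 2014, and the 2007-2009
    combined damaged/destroyed count feeds the structure fallback. Groups
    visible in no criteria source are omitted.
    """
    cfg = cfg or SimulationConfig()
    partition = truth_partition(fires)
    groups: dict[str, list[TruthFire]] = {}
    for fire in fires:
        groups.setdefault(partition[fire.truth_id], []).append(fire)

    outcomes = {}
    for gid, members in groups.items():
        visible = [
            m for m in members if m.in_ics209 or m.in_redbooks(cfg) or m.fmag
        ]
        if not visible:
            continue
        rb = [m for m in visible if m.in_redbooks(cfg)]
        ics = [m for m in visible if m.in_ics209]
        year = min(m.ignition_date for m in visible).year
        era_struct = 2007 <= year <= 2009

        if rb:
            civilian = sum(m.civilian_fatalities for m in rb)
            total = sum(m.total_fatalities for m in rb)
        elif ics:
            civilian = (
                sum(m.civilian_fatalities for m in ics) if year >= 2014 else None
            )
            total = sum(m.total_fatalities for m in ics)
        else:
            civilian = total = None

        if rb and not era_struct:
            destroyed = sum(m.destroyed_structures for m in rb)
        elif ics:
            destroyed = sum(m.destroyed_structures for m in ics)
        elif rb:
            destroyed = None  # era rows carry only the combined count
        else:
            destroyed = None
        combined = (
            sum(m.destroyed_structures + m.damaged_structures for m in rb)
            if rb and era_struct
            else None
        )

        fatality_met = (civilian or 0) >= 1 or (
            2000 <= year <= 2013 and (total or 0) >= 1
        )
        structure_met = (destroyed or 0) >= 1 or (
            era_struct and (combined or 0) >= 1
        )
        fmag_met = any(m.fmag for m in visible)

        has_origin = any(m.has_origin for m in ics)
        has_geometry = (
            any(m.in_mtbs and m.passes_mtbs_size(cfg.mtbs_rule) for m in members)
            or any(m.in_nifc for m in members)
            or (has_origin and any(m.in_fired for m in members))
            or has_origin
        )
        community = members[0].near_community if has_geometry else None

        outcomes[gid] = IntendedOutcome(
            group_id=gid,
            truth_ids=tuple(sorted(m.truth_id for m in members)),
            fatality_met=fatality_met,
            structure_met=structure_met,
            fmag_met=fmag_met,
            community_flag=community,
        )
    return outcomes
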