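"""Community-proximity classification for burn zones.

Smooths gridded population into a density surface, buffers each burn zone
by a size-dependent distance, takes the max/mean smoothed density inside
the buffer, and combines the density flag with wildland-urban-interface
overlap of the raw burn geometry into a single community flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry

from .grids import Grid
from .records import ExposureResult, GeometryAssignment

WUI_NONE = 0
WUI_INTERMIX = 1
WUI_INTERFACE = 2


@dataclass
class CommunityConfig:
    density_threshold: float = 96.0  # people / km^2
    smoothing_radius_m: float = 300.0
    small_buffer_m: float = 10_000.0
    large_buffer_m: float = 20_000.0
    size_threshold_acres: float = 1_000.0
    epoch_interval: int = 5

    def __post_init__(self) -> None:
        if self.small_buffer_m > self.large_buffer_m:
            raise ValueError("small_buffer must not exceed large_buffer")
        if min(
            self.density_threshold,
            self.smoothing_radius_m,
            self.small_buffer_m,
            self.size_threshold_acres,
            self.epoch_interval,
        ) <= 0:
            raise ValueError("all community thresholds must be positive")


def epoch_for_year(year: int, interval: int = 5) -> int:
    """Round a year to the nearest epoch multiple; ties round up."""
    import math

    return int(interval * math.floor(year / interval + 0.5))


def disk_offsets(radius_m: float, cell_size: float) -> np.ndarray:
    """Boolean footprint of cells whose centres lie within ``radius_m``."""
    if radius_m <= 0:
        raise ValueError("smoothing radius must be positive")
    reach = int(radius_m // cell_size)
    ii, jj = np.mgrid[-reach : reach + 1, -reach : reach + 1]
    return (ii**2 + jj**2) * cell_size**2 <= radius_m**2


def smooth_density(pop: Grid, radius_m: float = 300.0) -> Grid:
    """Population grid -> smoothed density surface in people/km^2.

    Per-cell density is population divided by the cell area; the smoothed
    value is the uniform-weight average of densities over all cells whose
    centres lie within the radius. Edge cells average over the in-bounds
    part of the footprint only, so a constant field is preserved exactly and
    the output is cellwise bounded by the raw density range.
    """
    cell_area_km2 = (pop.cell_size / 1000.0) ** 2
    density = pop.values.astype(float) / cell_area_km2
    footprint = disk_offsets(radius_m, pop.cell_size).astype(float)
    total = ndimage.convolve(density, footprint, mode="constant", cval=0.0)
    weight = ndimage.convolve(
        np.ones_like(density), footprint, mode="constant", cval=0.0
    )
    return pop.like(total / weight)


def buffer_zone(
    geometry: BaseGeometry,
    area_acres: Optional[float],
    cfg: Optional[CommunityConfig] = None,
) -> BaseGeometry:
    """Euclidean buffer: 10 km for small fires (< 1,000 acres, or a bare
    point of origin), 20 km for large fires (>= 1,000 acres)."""
    cfg = cfg or CommunityConfig()
    if isinstance(geometry, Point) or area_acres is None:
        distance = cfg.small_buffer_m
    elif area_acres >= cfg.size_threshold_acres:
        distance = cfg.large_buffer_m
    else:
        distance = cfg.small_buffer_m
    return geometry.buffer(distance)


def _cells_in_geometry(
    grid: Grid, geometry: BaseGeometry
) -> tuple[np.ndarray, np.ndarray]:
    """(rows, cols) of cells whose centres fall inside the geometry,
    restricted to the geometry's bounding window."""
    minx, miny, maxx, maxy = geometry.bounds
    xs, ys = grid.cell_centers()
    col_mask = (xs >= minx - grid.cell_size) & (xs <= maxx + grid.cell_size)
    row_mask = (ys >= miny - grid.cell_size) & (ys <= maxy + grid.cell_size)
    cols = np.nonzero(col_mask)[0]
    rows = np.nonzero(row_mask)[0]
    if len(cols) == 0 or len(rows) == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    cc, rr = np.meshgrid(cols, rows)
    px = xs[cc].ravel()
    py = ys[rr].ravel()
    shapely.prepare(geometry)
    inside = shapely.contains_xy(geometry, px, py)
    return rr.ravel()[inside], cc.ravel()[inside]


def density_exposure(
    buffered: BaseGeometry,
    smoothed: Grid,
    cfg: Optional[CommunityConfig] = None,
) -> tuple[float, float, bool, bool]:
    """Max and mean smoothed density over cells inside the buffered zone.

    Returns (max_density, mean_density, density_flag, out_of_extent). A
    buffer entirely outside the grid extent yields zeros with the
    out-of-extent flag set.
    """
    cfg = cfg or CommunityConfig()
    rows, cols = _cells_in_geometry(smoothed, buffered)
    if len(rows) == 0:
        return 0.0, 0.0, False, True
    values = smoothed.values[rows, cols]
    max_density = float(values.max())
    mean_density = float(values.mean())
    # tiny slack so convolution round-off cannot flip the >= threshold test
    flag = max_density >= cfg.density_threshold - 1e-9
    return max_density, mean_density, flag, False


def wui_overlap(geometry: BaseGeometry, wui: Grid) -> str:
    """WUI class of the raw (unbuffered) burn geometry.

    Evaluated on cells whose centres fall inside the geometry; a geometry
    covering no cell centre (points, slivers) falls back to the single cell
    containing its representative point.
    """
    rows, cols = _cells_in_geometry(wui, geometry)
    if len(rows) == 0:
        rep = geometry.representative_point()
        try:
            row, col = wui.index_of(rep.x, rep.y)
        except IndexError:
            return "none"
        rows = np.array([row])
        cols = np.array([col])
    classes = set(np.unique(wui.values[rows, cols]).astype(int))
    has_intermix = WUI_INTERMIX in classes
    has_interface = WUI_INTERFACE in classes
    if has_intermix and has_interface:
        return "both"
    if has_intermix:
        return "intermix"
    if has_interface:
        return "interface"
    return "none"


def classify_community(
    assignment: GeometryAssignment,
    wui: Optional[Grid],
    smoothed: Grid,
    ignition_year: Optional[int],
    cfg: Optional[CommunityConfig] = None,
) -> ExposureResult:
    """Full community-proximity decision for one geometry assignment.

    County-only records (no geometry) cannot be buffered; they get an
    unknown community flag and are excluded from the flagged subset while
    remaining in the full output.
    """
    cfg = cfg or CommunityConfig()
    if assignment.geometry is None:
        return ExposureResult(
            density_flag=None,
            community_flag=None,
            wui_class="none",
            epoch_year=None,
        )
    epoch = (
        epoch_for_year(ignition_year, cfg.epoch_interval)
        if ignition_year is not None
        else None
    )
    area_acres = (
        None
        if assignment.area_km2 is None
        else assignment.area_km2 / 0.0040468564224
    )
    buffered = buffer_zone(assignment.geometry, area_acres, cfg)
    max_d, mean_d, density_flag, out_of_extent = density_exposure(
        buffered, smoothed, cfg
    )
    wui_class = (
        wui_overlap(assignment.geometry, wui) if wui is not None else "none"
    )
    return ExposureResult(
        max_density=max_d,
        mean_density=mean_d,
        density_flag=density_flag,
        wui_class=wui_class,
        community_flag=density_flag or wui_class != "none",
        epoch_year=epoch,
        out_of_extent=out_of_extent,
    )
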