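"""Regular raster grids in the planar frame, with plain-text (ESRI ASCII) I/O.

Grids hold a 2-D array whose row 0 is the *northernmost* row, matching the
ASCII-grid convention. Cell (row, col) has its centre at::

    x = xllcorner + (col + 0.5) * cell_size
    y = yllcorner + (nrows - row - 0.5) * cell_size
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

NODATA = -9999


@dataclass
class Grid:
    values: np.ndarray  # shape (nrows, ncols), row 0 = north
    xllcorner: float
    yllcorner: float
    cell_size: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("grid values must be 2-D")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return (
            self.xllcorner,
            self.yllcorner,
            self.xllcorner + self.ncols * self.cell_size,
            self.yllcorner + self.nrows * self.cell_size,
        )

    def same_frame(self, other: "Grid") -> bool:
        return (
            self.values.shape == other.values.shape
            and self.xllcorner == other.xllcorner
            and self.yllcorner == other.yllcorner
            and self.cell_size == other.cell_size
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (xs, ys) 1-D arrays of column / row centre coordinates."""
        xs = self.xllcorner + (np.arange(self.ncols) + 0.5) * self.cell_size
        ys = (
            self.yllcorner
            + (self.nrows - np.arange(self.nrows) - 0.5) * self.cell_size
        )
        return xs, ys

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing planar point (x, y)."""
        col = int((x - self.xllcorner) // self.cell_size)
        row = self.nrows - 1 - int((y - self.yllcorner) // self.cell_size)
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            raise IndexError(f"point ({x}, {y}) outside grid extent")
        return row, col

    def like(self, values: np.ndarray) -> "Grid":
        if values.shape != self.values.shape:
            raise ValueError("shape mismatch")
        return Grid(values, self.xllcorner, self.yllcorner, self.cell_size)


def write_ascii(grid: Grid, path: str | Path, fmt: str = "%.10g") -> None:
    path = Path(path)
    header = (
        f"ncols {grid.ncols}\n"
        f"nrows {grid.nrows}\n"
        f"xllcorner {grid.xllcorner!r}\n"
        f"yllcorner {grid.yllcorner!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {NODATA}\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, grid.values, fmt=fmt)


def read_ascii(path: str | Path) -> Grid:
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        values = np.loadtxt(fh)
    values = np.atleast_2d(values)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"ASCII grid shape mismatch in {path}")
    return Grid(
        values,
        header["xllcorner"],
        header["yllcorner"],
        header["cellsize"],
    )
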