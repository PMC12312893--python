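"""Minimal raster support on a regular projected grid.

Rasters are numpy arrays on an axis-aligned grid in a projected, metre-based
coordinate system.  Internally row 0 is the *southernmost* row (y increases
with row index); the ESRI ASCII-grid text format stores rows north-to-south,
so I/O flips the array.  This container deliberately covers only what the
pipeline needs: nearest-cell extraction, cell centres, and text round-trips.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a raster grid: lower-left corner, shape and cell size."""

    x0: float
    y0: float
    nx: int
    ny: int
    resolution: float
    crs: str | None = None

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid must have at least one cell per axis")

    @classmethod
    def from_extent(
        cls,
        width_m: float,
        height_m: float,
        resolution: float,
        x0: float = 0.0,
        y0: float = 0.0,
        crs: str | None = None,
    ) -> "GridSpec":
        if resolution <= 0:
            raise ValueError("resolution must be positive")
        nx = width_m / resolution
        ny = height_m / resolution
        if abs(nx - round(nx)) > 1e-9 or abs(ny - round(ny)) > 1e-9:
            raise ValueError(
                f"extent {width_m} x {height_m} m is not divisible into whole "
                f"{resolution} m cells"
            )
        return cls(x0=x0, y0=y0, nx=int(round(nx)), ny=int(round(ny)),
                   resolution=resolution, crs=crs)

    @property
    def width(self) -> float:
        return self.nx * self.resolution

    @property
    def height(self) -> float:
        return self.ny * self.resolution

    @property
    def xmax(self) -> float:
        return self.x0 + self.width

    @property
    def ymax(self) -> float:
        return self.y0 + self.height

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """1-D arrays of cell-centre x (length nx) and y (length ny)."""
        xs = self.x0 + (np.arange(self.nx) + 0.5) * self.resolution
        ys = self.y0 + (np.arange(self.ny) + 0.5) * self.resolution
        return xs, ys

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(ny, nx) meshgrids of cell-centre coordinates."""
        xs, ys = self.cell_centers()
        return np.meshgrid(xs, ys)

    def index_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Row/column of the cell containing each point.

        Points exactly on the top/right edge map to the last cell; points
        outside the extent raise with the offending indices listed.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        eps = 1e-9 * self.resolution
        bad = (x < self.x0 - eps) | (x > self.xmax + eps) | \
              (y < self.y0 - eps) | (y > self.ymax + eps)
        if np.any(bad):
            idx = np.flatnonzero(bad)[:10]
            raise ValueError(f"points outside raster extent at indices {idx.tolist()}")
        col = np.clip(((x - self.x0) / self.resolution).astype(int), 0, self.nx - 1)
        row = np.clip(((y - self.y0) / self.resolution).astype(int), 0, self.ny - 1)
        return row, col

    def contains(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= self.x0) & (x <= self.xmax) & (y >= self.y0) & (y <= self.ymax)


@dataclass
class Raster:
    grid: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (self.grid.ny, self.grid.nx):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid "
                f"({self.grid.ny}, {self.grid.nx})"
            )

    def extract(self, x, y) -> np.ndarray:
        """Nearest-cell values at point coordinates."""
        row, col = self.grid.index_of(x, y)
        return self.values[row, col]

    def write_ascii(self, path) -> None:
        write_ascii_grid(self, path)

    @classmethod
    def read_ascii(cls, path) -> "Raster":
        return read_ascii_grid(path)


def write_ascii_grid(raster: Raster, path) -> None:
    """Write an ESRI ASCII grid (text, north-to-south row order)."""
    g = raster.grid
    vals = np.flipud(np.asarray(raster.values, dtype=float))
    header = (
        f"ncols {g.nx}\n"
        f"nrows {g.ny}\n"
        f"xllcorner {g.x0!r}\n"
        f"yllcorner {g.y0!r}\n"
        f"cellsize {g.resolution!r}\n"
        f"NODATA_value -9999\n"
    )
    body = np.where(np.isfinite(vals), vals, -9999.0)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt="%.10g")


def read_ascii_grid(path) -> Raster:
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        body = np.loadtxt(fh)
    grid = GridSpec(
        x0=header["xllcorner"],
        y0=header["yllcorner"],
        nx=int(header["ncols"]),
        ny=int(header["nrows"]),
        resolution=header["cellsize"],
    )
    body = np.atleast_2d(body)
    nodata = header.get("nodata_value")
    if nodata is not None:
        body = np.where(body == nodata, np.inf, body)
    return Raster(grid=grid, values=np.flipud(body))


def distance_raster_from_mask(mask: np.ndarray, resolution: float) -> np.ndarray:
    """Distance (m) from each cell to the nearest True cell of ``mask``.

    Cells inside the mask get 0; an empty mask yields +inf everywhere.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.full(mask.shape, np.inf)
    dist = ndimage.distance_transform_edt(~mask)
    return dist * resolution
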