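"""Regular longitude/latitude rasters.

Grid convention used throughout the package:

* cells are squares of ``resolution`` degrees on a side;
* ``lon_min`` / ``lat_min`` are the *outer edges* of the south-west cell,
  so the centre of cell ``(0, 0)`` sits at
  ``(lon_min + resolution / 2, lat_min + resolution / 2)``;
* ``values`` has shape ``(nrow, ncol)`` with **row 0 = southernmost row**;
* missing cells are ``NaN`` (the ``nodata`` marker).

A plain-text serialisation is provided (`write_grid_csv` / `read_grid_csv`):
a single header line ``lon_min,lat_min,resolution,ncol,nrow`` followed by the
values row-major from the southernmost row, NaN spelled ``nan``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["GridSpec", "GridSurface", "read_grid_csv", "write_grid_csv"]


@dataclass(frozen=True)
class GridSpec:
    """Extent and resolution of a raster, without values."""

    lon_min: float
    lat_min: float
    resolution: float
    ncol: int
    nrow: int

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        if self.ncol < 1 or self.nrow < 1:
            raise ValueError("grid must have at least one cell")

    @property
    def lon_max(self) -> float:
        return self.lon_min + self.ncol * self.resolution

    @property
    def lat_max(self) -> float:
        return self.lat_min + self.nrow * self.resolution

    def lon_centers(self) -> np.ndarray:
        return self.lon_min + (np.arange(self.ncol) + 0.5) * self.resolution

    def lat_centers(self) -> np.ndarray:
        return self.lat_min + (np.arange(self.nrow) + 0.5) * self.resolution

    def empty(self, fill: float = 0.0) -> "GridSurface":
        return GridSurface(
            lon_min=self.lon_min,
            lat_min=self.lat_min,
            resolution=self.resolution,
            values=np.full((self.nrow, self.ncol), fill, dtype=float),
        )

    def contains(self, lon: float, lat: float) -> bool:
        return (
            self.lon_min <= lon < self.lon_max
            and self.lat_min <= lat < self.lat_max
        )

    def cell_index(self, lon: float, lat: float) -> tuple[int, int]:
        """(row, col) of the cell containing the point; raises if outside."""
        if not self.contains(lon, lat):
            raise ValueError(f"point ({lon}, {lat}) outside grid extent")
        j = int((lon - self.lon_min) / self.resolution)
        i = int((lat - self.lat_min) / self.resolution)
        return min(i, self.nrow - 1), min(j, self.ncol - 1)


@dataclass
class GridSurface:
    """A single scalar field (density, isotope value, probability) on a grid."""

    lon_min: float
    lat_min: float
    resolution: float
    values: np.ndarray
    nodata: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")

    # -- geometry ----------------------------------------------------------
    @property
    def nrow(self) -> int:
        return self.values.shape[0]

    @property
    def ncol(self) -> int:
        return self.values.shape[1]

    @property
    def spec(self) -> GridSpec:
        return GridSpec(
            self.lon_min, self.lat_min, self.resolution, self.ncol, self.nrow
        )

    def lon_centers(self) -> np.ndarray:
        return self.spec.lon_centers()

    def lat_centers(self) -> np.ndarray:
        return self.spec.lat_centers()

    def cell_index(self, lon: float, lat: float) -> tuple[int, int]:
        return self.spec.cell_index(lon, lat)

    def value_at(self, lon: float, lat: float) -> float:
        i, j = self.cell_index(lon, lat)
        return float(self.values[i, j])

    # -- helpers -----------------------------------------------------------
    def copy(self) -> "GridSurface":
        return replace(self, values=self.values.copy())

    def with_values(self, values: np.ndarray) -> "GridSurface":
        values = np.asarray(values, dtype=float)
        if values.shape != self.values.shape:
            raise ValueError("replacement values must keep the grid shape")
        return replace(self, values=values)

    def valid_mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds data."""
        return np.isfinite(self.values)

    def aligned_with(self, other: "GridSurface") -> bool:
        return (
            np.isclose(self.lon_min, other.lon_min)
            and np.isclose(self.lat_min, other.lat_min)
            and np.isclose(self.resolution, other.resolution)
            and self.values.shape == other.values.shape
        )

    def require_aligned(self, other: "GridSurface", what: str = "surfaces") -> None:
        if not self.aligned_with(other):
            raise ValueError(f"{what} are on mismatched grids")

    @property
    def cell_area_deg2(self) -> float:
        return self.resolution**2

    def integral(self) -> float:
        """Discrete integral in value x deg^2 units, NaN cells skipped."""
        return float(np.nansum(self.values) * self.cell_area_deg2)


# ---------------------------------------------------------------------------
# text serialisation


def write_grid_csv(surface: GridSurface, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("lon_min,lat_min,resolution,ncol,nrow\n")
        fh.write(
            f"{surface.lon_min!r},{surface.lat_min!r},"
            f"{surface.resolution!r},{surface.ncol},{surface.nrow}\n"
        )
        for row in surface.values:
            fh.write(",".join(format(v, ".17g") for v in row) + "\n")


def read_grid_csv(path: str | Path) -> GridSurface:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip().split(",")
        if header[:5] != ["lon_min", "lat_min", "resolution", "ncol", "nrow"]:
            raise ValueError(f"{path}: not a grid CSV (bad header)")
        lon_min, lat_min, resolution, ncol, nrow = fh.readline().strip().split(",")
        values = np.loadtxt(fh, delimiter=",", ndmin=2)
    surface = GridSurface(
        lon_min=float(lon_min),
        lat_min=float(lat_min),
        resolution=float(resolution),
        values=values,
    )
    if surface.values.shape != (int(nrow), int(ncol)):
        raise ValueError(f"{path}: value block does not match declared shape")
    return surface
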