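"""Lightweight geographic grid containers and plain-text raster I/O.

All rasters in this package live on regular geographic (lon/lat) grids with
the origin at the upper-left corner, square pixels, and values located at
cell centres over half-open cell intervals.  Files are written as ESRI ASCII
grids (``.asc``), one band per file, with NaN encoded by the ``nodata``
value; multi-band products use one file per band plus a JSON sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Regular lon/lat grid: ``west``/``south`` outer edges, ``res`` degrees
    per pixel, ``ny`` rows (top row = northernmost) and ``nx`` columns."""

    west: float
    south: float
    res: float
    ny: int
    nx: int

    def __post_init__(self) -> None:
        if self.res <= 0:
            raise ValueError(f"grid resolution must be positive, got {self.res}")
        if self.ny <= 0 or self.nx <= 0:
            raise ValueError("grid must have positive dimensions")

    @property
    def north(self) -> float:
        return self.south + self.ny * self.res

    @property
    def east(self) -> float:
        return self.west + self.nx * self.res

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    def lon_centers(self) -> np.ndarray:
        return self.west + (np.arange(self.nx) + 0.5) * self.res

    def lat_centers(self) -> np.ndarray:
        # row 0 is the northernmost row
        return self.north - (np.arange(self.ny) + 0.5) * self.res

    def contains(self, lon, lat) -> np.ndarray:
        lon = np.asarray(lon)
        lat = np.asarray(lat)
        return (
            (lon >= self.west) & (lon < self.east)
            & (lat > self.south) & (lat <= self.north)
        )

    def index_of(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """Row/column of the pixel containing each point (half-open cells)."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.west) / self.res).astype(int)
        row = np.floor((self.north - lat) / self.res).astype(int)
        # points exactly on the north/west outer edge belong to the first cell
        col = np.clip(col, 0, self.nx - 1)
        row = np.clip(row, 0, self.ny - 1)
        inside = self.contains(lon, lat)
        if not np.all(inside):
            raise ValueError(
                f"{int(np.sum(~inside))} point(s) fall outside the grid extent"
            )
        return row, col

    def refine(self, factor: int) -> "GridSpec":
        """Grid with the same extent at ``factor``-times finer resolution."""
        if factor < 1:
            raise ValueError("refinement factor must be >= 1")
        return GridSpec(self.west, self.south, self.res / factor,
                        self.ny * factor, self.nx * factor)


@dataclass
class Raster:
    """Single-band float raster; missing values are NaN."""

    grid: GridSpec
    values: np.ndarray
    name: str = ""
    units: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    def sample(self, lon, lat) -> np.ndarray:
        row, col = self.grid.index_of(lon, lat)
        return self.values[row, col]

    def crop(self, rows: slice, cols: slice) -> "Raster":
        sub = self.values[rows, cols]
        r0 = rows.indices(self.grid.ny)[0]
        c0 = cols.indices(self.grid.nx)[0]
        g = GridSpec(
            west=self.grid.west + c0 * self.grid.res,
            south=self.grid.north - (r0 + sub.shape[0]) * self.grid.res,
            res=self.grid.res,
            ny=sub.shape[0],
            nx=sub.shape[1],
        )
        return Raster(g, sub.copy(), self.name, self.units, dict(self.meta))


@dataclass
class MonthlyClimateRaster:
    """Monthly climate stacks on a coarse grid: ``tas`` (°C), ``pr``
    (mm/month) and ``srad`` (kJ/m2/month), each shaped (12, ny, nx)."""

    grid: GridSpec
    tas: np.ndarray
    pr: np.ndarray
    srad: np.ndarray | None = None
    pet: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("tas", "pr", "srad", "pet"):
            arr = getattr(self, name)
            if arr is None:
                continue
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (12,) + self.grid.shape:
                raise ValueError(
                    f"{name} must be shaped (12, ny, nx)={(12,) + self.grid.shape}, "
                    f"got {arr.shape}")
            setattr(self, name, arr)


@dataclass
class LandCoverRaster:
    """Integer sub-class codes on a fine grid plus the code table
    (columns: ``class_name``, ``subclass_name``, ``natural``, indexed by
    integer code)."""

    grid: GridSpec
    codes: np.ndarray
    table: "object"  # pandas.DataFrame indexed by code

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.shape != self.grid.shape:
            raise ValueError("codes shape must match grid shape")
        unknown = set(np.unique(self.codes)) - set(self.table.index)
        if unknown:
            raise ValueError(f"codes missing from code table: {sorted(unknown)}")


def block_aggregate(values: np.ndarray, factor: int,
                    min_valid_fraction: float = 0.0) -> np.ndarray:
    """Coarsen a 2-D array by ``factor`` using the mean over valid (non-NaN)
    fine pixels per block; blocks whose valid fraction falls below
    ``min_valid_fraction`` (or with no valid pixel) become NaN."""
    values = np.asarray(values, dtype=float)
    ny, nx = values.shape
    if ny % factor or nx % factor:
        raise ValueError(f"shape {values.shape} not divisible by factor {factor}")
    blocks = values.reshape(ny // factor, factor, nx // factor, factor)
    blocks = blocks.transpose(0, 2, 1, 3).reshape(ny // factor, nx // factor, -1)
    valid = np.isfinite(blocks)
    nvalid = valid.sum(axis=-1)
    with np.errstate(invalid="ignore"):
        out = np.nanmean(blocks, axis=-1)
    frac = nvalid / (factor * factor)
    out[(nvalid == 0) | (frac < min_valid_fraction)] = np.nan
    return out


def write_asc(path: str | Path, raster: Raster, nodata: float = NODATA) -> None:
    vals = np.where(np.isfinite(raster.values), raster.values, nodata)
    g = raster.grid
    header = (
        f"ncols {g.nx}\nnrows {g.ny}\nxllcorner {g.west!r}\n"
        f"yllcorner {g.south!r}\ncellsize {g.res!r}\nNODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.10g")
    sidecar = Path(path).with_suffix(".json")
    meta = {"name": raster.name, "units": raster.units, **raster.meta}
    sidecar.write_text(json.dumps(meta, indent=1))


def read_asc(path: str | Path) -> Raster:
    with open(path) as fh:
        header: dict[str, float] = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        vals = np.loadtxt(fh)
    vals = np.atleast_2d(vals)
    vals[vals == header["nodata_value"]] = np.nan
    grid = GridSpec(
        west=header["xllcorner"], south=header["yllcorner"],
        res=header["cellsize"], ny=int(header["nrows"]), nx=int(header["ncols"]),
    )
    meta: dict = {}
    sidecar = Path(path).with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return Raster(grid, vals, meta.pop("name", ""), meta.pop("units", ""), meta)
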