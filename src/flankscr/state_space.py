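"""Discrete state space for activity centers: buffered grid + habitat mask.

The state space S is a regular square lattice of cell centroids covering
the trap array plus a buffer, chosen wide enough that no animal outside
S has an appreciable chance of detection (conventionally 2.5 sigma).
A binary habitat flag h_q marks cells with suitable habitat; activity
centers are supported only on suitable cells, and the same grid serves
as the integration grid for p*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .encounter_data import TrapArray


@dataclass
class HabitatGrid:
    """Regular grid of Q cell centroids with binary suitability flags."""

    centroids: np.ndarray   # (Q, 2) meters, row-major from the SW corner
    cell_size: float        # meters, square cells
    h: np.ndarray           # (Q,) 0/1 suitability
    nrow: int
    ncol: int
    xll: float              # lower-left corner of the gridded extent
    yll: float

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.h = np.asarray(self.h, dtype=np.int8)
        if self.centroids.shape != (self.nrow * self.ncol, 2):
            raise ValueError("centroids inconsistent with nrow*ncol")
        if self.h.shape != (self.centroids.shape[0],):
            raise ValueError("h must have one flag per cell")
        if not np.isin(self.h, (0, 1)).all():
            raise ValueError("h entries must be 0/1")
        if self.h.sum() < 1:
            raise ValueError("habitat mask leaves no suitable cell")

    @property
    def n_cells(self) -> int:
        return self.centroids.shape[0]

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_size / 1000.0) ** 2

    @property
    def total_area_km2(self) -> float:
        return self.n_cells * self.cell_area_km2

    @property
    def suitable_area_km2(self) -> float:
        return float(self.h.sum()) * self.cell_area_km2

    @property
    def suitable_cells(self) -> np.ndarray:
        """Indices of suitable cells (the support of activity centers)."""
        return np.flatnonzero(self.h == 1)

    def rowcol(self, cell: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return np.divmod(np.asarray(cell), self.ncol)

    def cell_at(self, row, col):
        return np.asarray(row) * self.ncol + np.asarray(col)

    def nearest_cell(self, xy: np.ndarray) -> np.ndarray:
        """Nearest centroid index for points (clipped to the grid extent)."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        col = np.clip(np.floor((xy[:, 0] - self.xll) / self.cell_size).astype(int),
                      0, self.ncol - 1)
        row = np.clip(np.floor((xy[:, 1] - self.yll) / self.cell_size).astype(int),
                      0, self.nrow - 1)
        return self.cell_at(row, col)


def build_grid(traps: TrapArray, buffer: float, cell_size: float) -> HabitatGrid:
    """Square lattice covering the trap bounding box plus ``buffer`` meters.

    All cells start suitable (h = 1); apply a mask afterwards with
    :func:`apply_mask`.  The number of cells per axis is rounded up so
    the lattice always covers the buffered extent.
    """
    if buffer <= 0:
        raise ValueError("buffer must be > 0")
    if cell_size <= 0:
        raise ValueError("cell_size must be > 0")
    xmin, ymin = traps.xy.min(axis=0) - buffer
    xmax, ymax = traps.xy.max(axis=0) + buffer
    ncol = max(1, math.ceil((xmax - xmin) / cell_size))
    nrow = max(1, math.ceil((ymax - ymin) / cell_size))
    # center the (possibly over-covering) lattice on the buffered extent
    xll = 0.5 * (xmin + xmax) - 0.5 * ncol * cell_size
    yll = 0.5 * (ymin + ymax) - 0.5 * nrow * cell_size
    xs = xll + (np.arange(ncol) + 0.5) * cell_size
    ys = yll + (np.arange(nrow) + 0.5) * cell_size
    gx, gy = np.meshgrid(xs, ys)
    centroids = np.column_stack([gx.ravel(), gy.ravel()])
    return HabitatGrid(centroids=centroids, cell_size=cell_size,
                       h=np.ones(nrow * ncol, dtype=np.int8),
                       nrow=nrow, ncol=ncol, xll=xll, yll=yll)


def apply_mask(grid: HabitatGrid, mask) -> HabitatGrid:
    """Return a copy of ``grid`` with updated suitability flags.

    ``mask`` is either a length-Q 0/1 vector aligned to the grid, or an
    :class:`AsciiRaster` covering the grid extent (nearest-cell lookup).
    """
    if isinstance(mask, AsciiRaster):
        h = mask.sample(grid.centroids)
    else:
        h = np.asarray(mask, dtype=np.int8)
        if h.shape != (grid.n_cells,):
            raise ValueError(f"mask length {h.shape} != Q = {grid.n_cells}")
    if not np.isin(h, (0, 1)).all():
        raise ValueError("mask entries must be 0/1")
    if h.sum() < 1:
        raise ValueError("mask leaves no suitable cell (no activity-center support)")
    return HabitatGrid(centroids=grid.centroids.copy(), cell_size=grid.cell_size,
                       h=h, nrow=grid.nrow, ncol=grid.ncol,
                       xll=grid.xll, yll=grid.yll)


# ---------------------------------------------------------------------------
# Raster / CSV habitat I/O

@dataclass
class AsciiRaster:
    """Minimal ESRI ASCII grid (values interpreted as 0/1 suitability)."""

    values: np.ndarray  # (nrows, ncols), row 0 = northernmost
    xll: float
    yll: float
    cellsize: float
    nodata: float = -9999.0

    def sample(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(xy)
        nrows, ncols = self.values.shape
        col = np.floor((xy[:, 0] - self.xll) / self.cellsize).astype(int)
        row_s = np.floor((xy[:, 1] - self.yll) / self.cellsize).astype(int)
        if (col < 0).any() or (col >= ncols).any() or (row_s < 0).any() or (row_s >= nrows).any():
            raise ValueError("raster does not cover the grid extent")
        vals = self.values[nrows - 1 - row_s, col]
        out = np.where(vals == self.nodata, 0, vals)
        return (out > 0).astype(np.int8)


def read_habitat_asc(path) -> AsciiRaster:
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0].lower() in ("ncols", "nrows", "xllcorner", "yllcorner",
                                    "cellsize", "nodata_value"):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"ASCII grid missing header field {key!r}")
    values = np.asarray(rows, dtype=float)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("ASCII grid data shape does not match header")
    return AsciiRaster(values=values, xll=header["xllcorner"], yll=header["yllcorner"],
                       cellsize=header["cellsize"],
                       nodata=header.get("nodata_value", -9999.0))


def write_habitat_asc(grid: HabitatGrid, path, values: np.ndarray | None = None) -> None:
    vals = grid.h if values is None else np.asarray(values)
    mat = vals.reshape(grid.nrow, grid.ncol)[::-1]  # row 0 = northernmost
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncol}\n")
        fh.write(f"nrows {grid.nrow}\n")
        fh.write(f"xllcorner {grid.xll}\n")
        fh.write(f"yllcorner {grid.yll}\n")
        fh.write(f"cellsize {grid.cell_size}\n")
        fh.write("NODATA_value -9999\n")
        for row in mat:
            fh.write(" ".join(format(v, "g") for v in row) + "\n")


def read_habitat_csv(path, grid: HabitatGrid) -> np.ndarray:
    """Per-cell flags from a CSV with columns x, y, h (nearest centroid)."""
    df = pd.read_csv(path)
    missing = {"x", "y", "h"} - set(df.columns)
    if missing:
        raise ValueError(f"habitat CSV missing columns: {sorted(missing)}")
    h = np.zeros(grid.n_cells, dtype=np.int8)
    cells = grid.nearest_cell(df[["x", "y"]].to_numpy(float))
    h[cells] = df["h"].to_numpy(int).astype(np.int8)
    return h
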