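"""Gridded raster containers and plain-text raster I/O.

A :class:`RasterGrid` is a single-band georeferenced grid: a 2-D value
array, an affine north-up transform (top-left origin plus square cell
size) and a boolean nodata mask.  Grids live either in projected metre
coordinates or in geographic degrees; the two behave identically except
for distance and area computations, which downstream code dispatches on
``crs_kind``.

Rasters are read and written as ESRI ASCII grids (``.asc``) — a
self-describing plain-text format that any GIS opens directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GridTransform",
    "RasterGrid",
    "PredictorStack",
    "SuitabilityMap",
    "read_ascii_grid",
    "write_ascii_grid",
    "align_stack",
    "EARTH_RADIUS_KM",
]

#: Mean Earth radius (IUGG), used for all spherical distance/area work.
EARTH_RADIUS_KM = 6371.0088

PROJECTED = "projected-metres"
GEOGRAPHIC = "geographic-degrees"
_CRS_KINDS = (PROJECTED, GEOGRAPHIC)


@dataclass(frozen=True)
class GridTransform:
    """North-up affine transform: top-left corner and square cell size."""

    x_min: float
    y_max: float
    cell_size: float

    def __post_init__(self) -> None:
        if not (self.cell_size > 0):
            raise ValueError(f"cell size must be positive, got {self.cell_size}")

    def cell_centers(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) 1-D center coordinates for columns and rows."""
        rows, cols = shape
        xs = self.x_min + (np.arange(cols) + 0.5) * self.cell_size
        ys = self.y_max - (np.arange(rows) + 0.5) * self.cell_size
        return xs, ys

    def index(self, x: np.ndarray, y: np.ndarray, shape: tuple[int, int]):
        """Map coordinates to (row, col) under the half-open cell convention.

        Cells include their left and top edges; row 0 is the north edge.
        Points outside the extent get index -1 in the offending axis.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x_min) / self.cell_size).astype(int)
        row = np.floor((self.y_max - y) / self.cell_size).astype(int)
        # the exact bottom/right boundary belongs to the last cell
        rows, cols = shape
        col = np.where((x == self.x_min + cols * self.cell_size), cols - 1, col)
        row = np.where((y == self.y_max - rows * self.cell_size), rows - 1, row)
        bad = (col < 0) | (col >= cols) | (row < 0) | (row >= rows)
        col = np.where(bad, -1, col)
        row = np.where(bad, -1, row)
        return row, col


@dataclass
class RasterGrid:
    """A single-band raster: values, transform, CRS kind and nodata mask."""

    values: np.ndarray
    transform: GridTransform
    crs_kind: str = PROJECTED
    mask: np.ndarray | None = None  # True where nodata

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.crs_kind not in _CRS_KINDS:
            raise ValueError(f"crs_kind must be one of {_CRS_KINDS}")
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask and values shapes differ")
            self.mask = self.mask | ~np.isfinite(self.values)
        if not np.all(np.isfinite(self.values[~self.mask])):
            raise ValueError("non-finite values outside the nodata mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid(self) -> np.ndarray:
        """Boolean array, True where the cell carries data."""
        return ~self.mask

    def with_values(self, values: np.ndarray, mask: np.ndarray | None = None) -> "RasterGrid":
        return RasterGrid(values, self.transform, self.crs_kind,
                          self.mask.copy() if mask is None else mask)

    def same_grid(self, other: "RasterGrid") -> bool:
        return (self.shape == other.shape
                and self.transform == other.transform
                and self.crs_kind == other.crs_kind)

    def cell_area_km2(self) -> np.ndarray:
        """Per-row cell area in km²; cosine-corrected for geographic grids."""
        rows, cols = self.shape
        if self.crs_kind == PROJECTED:
            a = (self.transform.cell_size / 1000.0) ** 2
            return np.full(rows, a)
        _, ys = self.transform.cell_centers(self.shape)
        km_per_deg = math.pi * EARTH_RADIUS_KM / 180.0
        side = self.transform.cell_size * km_per_deg
        return side * side * np.cos(np.radians(ys))


@dataclass
class PredictorStack:
    """Named, mutually aligned environmental layers sharing grid and mask.

    The stack mask is the union of the member masks, applied to all layers.
    """

    layers: dict[str, RasterGrid]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("empty predictor stack")
        ref = next(iter(self.layers.values()))
        for name, g in self.layers.items():
            if not g.same_grid(ref):
                raise ValueError(f"layer {name!r} is not aligned with the stack")
        union = np.zeros(ref.shape, dtype=bool)
        for g in self.layers.values():
            union |= g.mask
        self.layers = {n: g.with_values(g.values, union.copy())
                       for n, g in self.layers.items()}

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def grid(self) -> RasterGrid:
        return next(iter(self.layers.values()))

    @property
    def transform(self) -> GridTransform:
        return self.grid.transform

    @property
    def crs_kind(self) -> str:
        return self.grid.crs_kind

    @property
    def mask(self) -> np.ndarray:
        return self.grid.mask

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def table(self) -> np.ndarray:
        """Valid-cell values as an (n_valid, n_layers) array, row-major order."""
        ok = self.grid.valid
        return np.column_stack([self.layers[n].values[ok] for n in self.names])

    def __getitem__(self, name: str) -> RasterGrid:
        return self.layers[name]


@dataclass
class SuitabilityMap:
    """A continuous suitability raster in [0, 1], optionally binarized."""

    grid: RasterGrid
    threshold: float | None = None
    binary: RasterGrid | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.grid.values[self.grid.valid]
        if vals.size and (vals.min() < -1e-9 or vals.max() > 1 + 1e-9):
            raise ValueError("suitability values must lie in [0, 1]")


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O

def write_ascii_grid(grid: RasterGrid, path: str | Path, nodata: float = -9999.0,
                     fmt: str = "%.8g") -> None:
    """Write a raster as an ESRI ASCII grid with an explicit nodata value."""
    path = Path(path)
    rows, cols = grid.shape
    vals = np.where(grid.mask, nodata, grid.values)
    header = (
        f"ncols {cols}\n"
        f"nrows {rows}\n"
        f"xllcorner {grid.transform.x_min!r}\n"
        f"yllcorner {grid.transform.y_max - rows * grid.transform.cell_size!r}\n"
        f"cellsize {grid.transform.cell_size!r}\n"
        f"NODATA_value {nodata!r}\n"
        f"# crs_kind {grid.crs_kind}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt=fmt)


def read_ascii_grid(path: str | Path, crs_kind: str | None = None) -> RasterGrid:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`.

    ``crs_kind`` is taken from the trailing header comment when present,
    defaulting to projected metres.
    """
    path = Path(path)
    header: dict[str, float] = {}
    kind = crs_kind
    with open(path) as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            if not line:
                raise ValueError(f"{path}: truncated ASCII grid")
            parts = line.split()
            if line.startswith("#"):
                if len(parts) >= 3 and parts[1] == "crs_kind" and kind is None:
                    kind = parts[2]
                continue
            if len(parts) == 2 and parts[0].lower() in (
                    "ncols", "nrows", "xllcorner", "yllcorner",
                    "cellsize", "nodata_value"):
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        vals = np.loadtxt(fh, ndmin=2)
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing header field {key}")
    rows, cols = int(header["nrows"]), int(header["ncols"])
    if vals.shape != (rows, cols):
        raise ValueError(f"{path}: data shape {vals.shape} != header ({rows}, {cols})")
    nodata = header.get("nodata_value")
    mask = np.zeros_like(vals, dtype=bool) if nodata is None else np.isclose(vals, nodata)
    tr = GridTransform(header["xllcorner"],
                       header["yllcorner"] + rows * header["cellsize"],
                       header["cellsize"])
    vals = np.where(mask, np.nan, vals)
    return RasterGrid(vals, tr, kind or PROJECTED, mask)


# ---------------------------------------------------------------------------
# Alignment

def align_stack(layers: Mapping[str, RasterGrid],
                reference: str | None = None) -> PredictorStack:
    """Resample layers onto a reference grid and crop to the common extent.

    Nearest-neighbour resampling onto the grid of ``reference`` (default:
    the first layer); the output carries the union-of-nodata mask.  Layers
    with disjoint extents are rejected.
    """
    if not layers:
        raise ValueError("no layers to align")
    names = list(layers)
    ref_name = reference or names[0]
    ref = layers[ref_name]
    cs = ref.transform.cell_size
    # common extent across all layers
    x0 = max(g.transform.x_min for g in layers.values())
    y1 = min(g.transform.y_max for g in layers.values())
    x1 = min(g.transform.x_min + g.shape[1] * g.transform.cell_size
             for g in layers.values())
    y0 = max(g.transform.y_max - g.shape[0] * g.transform.cell_size
             for g in layers.values())
    if x1 <= x0 or y1 <= y0:
        raise ValueError("layer extents are disjoint; nothing to align")
    # snap the common window to the reference grid
    col0 = int(math.floor((x0 - ref.transform.x_min) / cs + 1e-9))
    row0 = int(math.floor((ref.transform.y_max - y1) / cs + 1e-9))
    col0, row0 = max(col0, 0), max(row0, 0)
    ncols = int(math.floor((x1 - (ref.transform.x_min + col0 * cs)) / cs + 1e-9))
    nrows = int(math.floor(((ref.transform.y_max - row0 * cs) - y0) / cs + 1e-9))
    if ncols < 1 or nrows < 1:
        raise ValueError("common extent smaller than one reference cell")
    out_tr = GridTransform(ref.transform.x_min + col0 * cs,
                           ref.transform.y_max - row0 * cs, cs)
    xs, ys = out_tr.cell_centers((nrows, ncols))
    xx, yy = np.meshgrid(xs, ys)
    out: dict[str, RasterGrid] = {}
    for name in names:
        g = layers[name]
        r, c = g.transform.index(xx.ravel(), yy.ravel(), g.shape)
        vals = np.full(r.shape, np.nan)
        inside = (r >= 0) & (c >= 0)
        vals[inside] = g.values[r[inside], c[inside]]
        m = ~inside
        m[inside] = g.mask[r[inside], c[inside]]
        out[name] = RasterGrid(vals.reshape(nrows, ncols), out_tr, g.crs_kind,
                               m.reshape(nrows, ncols))
    return PredictorStack(out)
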