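"""Terrain derivatives and collinearity screening for predictor stacks.

Slope follows Horn's 8-neighbour weighted finite differences, the method
behind the classic raster ``terrain`` routines.  Topographic
heterogeneity (TH) is the sample standard deviation of fine-scale
elevation aggregated into coarse blocks — e.g. the SD of 90 m elevation
cells within each 1 km cell — a simple ruggedness measure.  Collinearity
among candidate predictors is screened with stepwise variance-inflation-
factor (VIF) elimination: VIF_j = 1/(1 − R²_j) with R²_j from ordinary
least squares of predictor j on all the others, iteratively dropping the
worst predictor until every VIF falls below the threshold (default 10).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .raster import EARTH_RADIUS_KM, GEOGRAPHIC, GridTransform, RasterGrid

__all__ = [
    "compute_slope",
    "compute_topographic_heterogeneity",
    "VIFReport",
    "vif_stepwise",
]

logger = logging.getLogger(__name__)

# Horn kernel weights for the 8 neighbours, by (dr, dc) offset.
_HORN_X = {(-1, -1): -1, (0, -1): -2, (1, -1): -1,
           (-1, 1): 1, (0, 1): 2, (1, 1): 1}
_HORN_Y = {(-1, -1): 1, (-1, 0): 2, (-1, 1): 1,
           (1, -1): -1, (1, 0): -2, (1, 1): -1}


def _shift(a: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Shift with edge replication so border cells see themselves."""
    out = np.roll(a, (dr, dc), axis=(0, 1))
    if dr > 0:
        out[:dr, :] = out[dr, :]
    elif dr < 0:
        out[dr:, :] = out[dr - 1, :]
    if dc > 0:
        out[:, :dc] = out[:, dc:dc + 1]
    elif dc < 0:
        out[:, dc:] = out[:, dc - 1:dc]
    return out


def compute_slope(elevation: RasterGrid) -> RasterGrid:
    """Slope in degrees via Horn's 8-neighbour weighted differences.

    Cell spacing is the grid cell size for projected-metre grids; for
    geographic grids, degree spacing is converted to metres per row with
    the local metres-per-degree at the row's latitude (spherical model).
    Border cells and cells with any nodata neighbour are masked rather
    than estimated from fewer neighbours.
    """
    rows, cols = elevation.shape
    if rows < 3 or cols < 3:
        raise ValueError("slope needs at least a 3×3 elevation raster")
    z = np.where(elevation.mask, np.nan, elevation.values)
    gx = np.zeros_like(z)
    gy = np.zeros_like(z)
    bad = elevation.mask.copy()
    for (dr, dc), w in _HORN_X.items():
        nb = _shift(z, -dr, -dc)   # value of the neighbour at offset (dr, dc)
        gx += w * nb
        bad |= ~np.isfinite(nb)
    for (dr, dc), w in _HORN_Y.items():
        nb = _shift(z, -dr, -dc)
        gy += w * nb
        bad |= ~np.isfinite(nb)
    cs = elevation.transform.cell_size
    if elevation.crs_kind == GEOGRAPHIC:
        m_per_deg = math.pi * EARTH_RADIUS_KM * 1000.0 / 180.0
        _, ys = elevation.transform.cell_centers(elevation.shape)
        dx = cs * m_per_deg * np.cos(np.radians(ys))[:, None]
        dy = cs * m_per_deg
    else:
        dx = cs
        dy = cs
    dzdx = gx / (8.0 * dx)
    dzdy = gy / (8.0 * dy)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    # mask borders and nodata-adjacent cells
    bad[0, :] = bad[-1, :] = True
    bad[:, 0] = bad[:, -1] = True
    slope = np.where(bad, np.nan, slope)
    return RasterGrid(slope, elevation.transform, elevation.crs_kind, bad)


def compute_topographic_heterogeneity(elevation_fine: RasterGrid,
                                      block: int) -> RasterGrid:
    """Aggregate fine elevation into blocks of the sample SD (n − 1).

    Each output cell covers ``block`` × ``block`` fine cells.  Partial
    edge blocks use the available cells when at least two are valid,
    otherwise they are masked.  TH is invariant under adding a constant
    to the elevation and scales linearly with it.
    """
    if block < 2:
        raise ValueError("block must cover at least 2 fine cells per side")
    rows, cols = elevation_fine.shape
    if block > rows or block > cols:
        raise ValueError("block larger than the elevation raster")
    out_rows = math.ceil(rows / block)
    out_cols = math.ceil(cols / block)
    z = np.where(elevation_fine.mask, np.nan, elevation_fine.values)
    vals = np.full((out_rows, out_cols), np.nan)
    for i in range(out_rows):
        for j in range(out_cols):
            blk = z[i * block:(i + 1) * block, j * block:(j + 1) * block]
            ok = np.isfinite(blk)
            if ok.sum() >= 2:
                vals[i, j] = np.std(blk[ok], ddof=1)
    tr = elevation_fine.transform
    coarse_tr = GridTransform(tr.x_min, tr.y_max, tr.cell_size * block)
    return RasterGrid(vals, coarse_tr, elevation_fine.crs_kind,
                      ~np.isfinite(vals))


@dataclass
class VIFReport:
    """Outcome of stepwise VIF screening."""

    vif: dict[str, float]              # final VIFs of the retained predictors
    removed: list[str]                 # removal order, worst first
    threshold: float
    history: list[dict[str, float]] = field(default_factory=list)

    @property
    def retained(self) -> list[str]:
        return list(self.vif)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"vif": self.vif, "removed": self.removed,
             "threshold": self.threshold}, indent=2))


def _vif_once(X: np.ndarray) -> np.ndarray:
    """VIF of each column: 1/(1 − R²) from OLS on the remaining columns."""
    n, p = X.shape
    out = np.empty(p)
    ones = np.ones((n, 1))
    for j in range(p):
        yj = X[:, j]
        others = np.hstack([ones, np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        sst = np.sum((yj - yj.mean()) ** 2)
        r2 = 1.0 - resid @ resid / sst
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def vif_stepwise(values: pd.DataFrame, threshold: float = 10.0) -> VIFReport:
    """Iteratively drop the max-VIF predictor until all VIFs < threshold.

    Exactly collinear predictors yield infinite VIF; the later-listed
    member of such a pair is removed first.  Constant columns are
    rejected (their VIF is undefined).
    """
    if values.shape[1] < 2:
        raise ValueError("need at least two predictor columns")
    if values.shape[0] < values.shape[1] + 2:
        raise ValueError("need at least p + 2 rows for VIF")
    const = [c for c in values.columns if values[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant columns cannot be screened: {const}")
    cols = list(values.columns)
    removed: list[str] = []
    history: list[dict[str, float]] = []
    while len(cols) >= 2:
        X = values[cols].to_numpy(dtype=float)
        v = _vif_once(X)
        history.append(dict(zip(cols, v)))
        if np.nanmax(v) < threshold:
            break
        # drop the worst; among ties on +inf prefer the later-listed column
        worst = np.flatnonzero(v == v.max())[-1]
        removed.append(cols.pop(worst))
        logger.info("VIF stepwise: removed %s (VIF %.4g)", removed[-1],
                    history[-1][removed[-1]])
    X = values[cols].to_numpy(dtype=float)
    final = dict(zip(cols, _vif_once(X))) if len(cols) >= 2 else {cols[0]: 1.0}
    return VIFReport(vif={k: float(x) for k, x in final.items()},
                     removed=removed, threshold=threshold, history=history)
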