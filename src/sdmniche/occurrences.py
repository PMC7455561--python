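"""Occurrence-record ingestion, de-duplication and spatial thinning.

Occurrence data for presence-only modelling typically arrive as delimited
text with one point per row.  Before modelling they are cleaned in three
stages — raw → deduplicated → thinned — mirroring the bookkeeping style
of field studies that report record counts at each stage.  Spatial
thinning enforces a minimum pairwise distance (default 5 km) between all
retained records to reduce spatial sampling autocorrelation; the
randomized-greedy algorithm below repeatedly removes the point with the
most remaining conflicts and keeps, over many seeded restarts, the run
that retains the most points.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .raster import EARTH_RADIUS_KM, GEOGRAPHIC, PROJECTED, PredictorStack

__all__ = [
    "OccurrenceSet",
    "read_occurrences",
    "write_occurrences",
    "deduplicate",
    "spatial_thin",
    "extract_env_values",
    "haversine_km",
    "pairwise_distance_km",
]

logger = logging.getLogger(__name__)

STAGES = ("raw", "deduplicated", "thinned")


@dataclass
class OccurrenceSet:
    """Georeferenced presence points with a processing-stage flag."""

    xy: np.ndarray                     # (n, 2) columns x (lon or m), y (lat or m)
    species_label: str = "species"
    stage: str = "raw"
    crs_kind: str = GEOGRAPHIC

    def __post_init__(self) -> None:
        self.xy = np.atleast_2d(np.asarray(self.xy, dtype=float))
        if self.xy.size == 0:
            self.xy = self.xy.reshape(0, 2)
        if self.xy.shape[1] != 2:
            raise ValueError("xy must have two columns")
        if not np.all(np.isfinite(self.xy)):
            raise ValueError("occurrence coordinates must be finite")
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}")

    def __len__(self) -> int:
        return self.xy.shape[0]

    def subset(self, idx, stage: str | None = None) -> "OccurrenceSet":
        return OccurrenceSet(self.xy[idx], self.species_label,
                             stage or self.stage, self.crs_kind)


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km on a sphere of radius 6,371.0088 km."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def pairwise_distance_km(occ: OccurrenceSet) -> np.ndarray:
    """Full pairwise distance matrix in km (great-circle or Euclidean)."""
    xy = occ.xy
    if occ.crs_kind == GEOGRAPHIC:
        return haversine_km(xy[:, 0:1], xy[:, 1:2], xy[None, :, 0], xy[None, :, 1])
    d = xy[:, None, :] - xy[None, :, :]
    return np.sqrt((d ** 2).sum(axis=-1)) / 1000.0


def read_occurrences(path: str | Path, species_label: str | None = None,
                     x_col: str = "lon", y_col: str = "lat",
                     crs_kind: str = GEOGRAPHIC, sep: str = ",") -> OccurrenceSet:
    """Parse a delimited-text file of points; malformed rows are skipped.

    Rows with unparseable or out-of-range coordinates (|lat| > 90 or
    |lon| > 180 on geographic data) are dropped with a logged count.
    """
    df = pd.read_csv(path, sep=sep)
    if x_col not in df.columns and crs_kind == PROJECTED:
        x_col, y_col = "x", "y"
    if x_col not in df.columns or y_col not in df.columns:
        raise ValueError(
            f"{path}: coordinate columns {x_col!r}/{y_col!r} not found "
            f"(have {list(df.columns)})")
    if len(df) == 0:
        raise ValueError(f"{path}: no records")
    x = pd.to_numeric(df[x_col], errors="coerce")
    y = pd.to_numeric(df[y_col], errors="coerce")
    ok = np.isfinite(x) & np.isfinite(y)
    if crs_kind == GEOGRAPHIC:
        ok &= (np.abs(x) <= 180) & (np.abs(y) <= 90)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("%s: skipped %d malformed/out-of-range rows", path, n_bad)
    if species_label is None:
        species_label = (str(df["species"].iloc[0])
                         if "species" in df.columns else Path(path).stem)
    return OccurrenceSet(np.column_stack([x[ok], y[ok]]), species_label,
                         "raw", crs_kind)


def write_occurrences(occ: OccurrenceSet, path: str | Path) -> None:
    cols = ("lon", "lat") if occ.crs_kind == GEOGRAPHIC else ("x", "y")
    df = pd.DataFrame({"species": occ.species_label,
                       cols[0]: occ.xy[:, 0], cols[1]: occ.xy[:, 1],
                       "stage": occ.stage})
    df.to_csv(path, index=False, float_format="%.10g")


def deduplicate(occ: OccurrenceSet, cell_size: float) -> OccurrenceSet:
    """Keep at most one record per grid cell of side ``cell_size`` (map units).

    The first record encountered in each cell is retained, so the
    operation is deterministic.  Exact duplicate coordinates always
    collapse to one record.
    """
    if occ.stage != "raw":
        raise ValueError("deduplicate expects a raw occurrence set")
    if not (cell_size > 0):
        raise ValueError("cell_size must be positive")
    keys = np.floor(occ.xy / cell_size).astype(np.int64)
    _, first = np.unique(keys, axis=0, return_index=True)
    keep = np.sort(first)
    logger.info("%s: deduplicated %d -> %d records", occ.species_label,
                len(occ), keep.size)
    return occ.subset(keep, stage="deduplicated")


def _greedy_thin(dist: np.ndarray, min_dist: float,
                 rng: np.random.Generator) -> np.ndarray:
    """One randomized-greedy pass: drop the max-conflict point until clean."""
    n = dist.shape[0]
    conflict = (dist < min_dist) & ~np.eye(n, dtype=bool)
    alive = np.ones(n, dtype=bool)
    counts = conflict.sum(axis=1).astype(float)
    while True:
        worst = counts[alive].max() if alive.any() else 0
        if worst == 0:
            break
        cand = np.flatnonzero(alive & (counts == worst))
        drop = cand[rng.integers(cand.size)]
        alive[drop] = False
        counts[conflict[drop]] -= 1
        counts[drop] = 0
    return np.flatnonzero(alive)


def spatial_thin(occ: OccurrenceSet, min_dist: float = 5.0,
                 rng_seed: int = 0, n_repeats: int = 100) -> OccurrenceSet:
    """Thin records so that all pairwise distances are >= ``min_dist`` km.

    Runs ``n_repeats`` randomized greedy passes (ties in conflict counts
    broken by the seeded RNG) and returns the pass retaining the most
    points — a standard approximation to maximum retention.  Distances
    are great-circle for geographic coordinates, Euclidean for projected.
    """
    if not (min_dist > 0):
        raise ValueError("min_dist must be positive")
    if len(occ) <= 1:
        return replace(occ, stage="thinned")
    dist = pairwise_distance_km(occ)
    rng = np.random.default_rng(rng_seed)
    best: np.ndarray | None = None
    for _ in range(max(1, n_repeats)):
        kept = _greedy_thin(dist, min_dist, rng)
        if best is None or kept.size > best.size:
            best = kept
    logger.info("%s: thinned %d -> %d records at %.3g km",
                occ.species_label, len(occ), best.size, min_dist)
    return occ.subset(best, stage="thinned")


def extract_env_values(occ: OccurrenceSet, stack: PredictorStack) -> pd.DataFrame:
    """Extract the containing cell's value per point and predictor.

    No interpolation: a point takes the value of the cell it falls in
    (half-open cells, top/left edges inclusive).  Points outside the
    extent or in nodata cells are excluded with a logged count; the
    returned frame carries the surviving points' row indices.
    """
    if occ.crs_kind != stack.crs_kind:
        raise ValueError(
            f"occurrences are {occ.crs_kind} but stack is {stack.crs_kind}")
    g = stack.grid
    r, c = g.transform.index(occ.xy[:, 0], occ.xy[:, 1], g.shape)
    inside = (r >= 0) & (c >= 0)
    valid = inside.copy()
    valid[inside] &= g.valid[r[inside], c[inside]]
    n_out = int((~inside).sum())
    n_nod = int(inside.sum() - valid.sum())
    if n_out or n_nod:
        logger.warning("%s: excluded %d points outside extent, %d in nodata cells",
                       occ.species_label, n_out, n_nod)
    idx = np.flatnonzero(valid)
    data = {name: stack[name].values[r[idx], c[idx]] for name in stack.names}
    return pd.DataFrame(data, index=idx)
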