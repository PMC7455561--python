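"""Niche overlap between suitability surfaces.

Schoener's D compares two habitat-suitability rasters treated as
probability distributions over the landscape:

    D(p, q) = 1 − ½ Σ_i |p_i − q_i|

after each surface is normalized to sum to 1 over the cells valid in
both.  D ranges from 0 (disjoint niches) to 1 (identical niches).  The
Hellinger-based I statistic,

    I(p, q) = 1 − ½ Σ_i (√p_i − √q_i)²,

is reported as a companion metric, as in the common niche-overlap
toolkits.  Both are symmetric; overlap is computed on continuous
(typically ensemble) suitability, not on binarized maps, which is what
gives the 0–1 semantics meaning.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .raster import RasterGrid, SuitabilityMap

__all__ = [
    "OverlapResult",
    "normalize_suitability",
    "schoeners_d",
    "hellinger_i",
    "overlap_matrix",
]


@dataclass
class OverlapResult:
    """Pairwise overlap between two named suitability surfaces."""

    species_a: str
    species_b: str
    schoener_d: float
    hellinger_i: float
    n_cells: int


def _common_valid(a: SuitabilityMap | RasterGrid,
                  b: SuitabilityMap | RasterGrid) -> np.ndarray:
    ga = a.grid if isinstance(a, SuitabilityMap) else a
    gb = b.grid if isinstance(b, SuitabilityMap) else b
    if not ga.same_grid(gb):
        raise ValueError("surfaces are on different grids; align them first")
    return ga.valid & gb.valid


def normalize_suitability(suit: SuitabilityMap | RasterGrid,
                          valid: np.ndarray | None = None) -> np.ndarray:
    """Valid-cell suitability as a probability vector summing to 1.

    Scale-invariant and idempotent; an all-zero surface is rejected.
    ``valid`` restricts normalization to a shared support when two
    surfaces are compared.
    """
    g = suit.grid if isinstance(suit, SuitabilityMap) else suit
    ok = g.valid if valid is None else valid
    v = np.nan_to_num(g.values, nan=0.0)[ok].astype(float)
    total = v.sum()
    if total <= 0:
        raise ValueError("cannot normalize an all-zero suitability surface")
    return v / total


def schoeners_d(p: np.ndarray, q: np.ndarray) -> float:
    """D = 1 − ½ Σ|p_i − q_i| for two probability vectors on one support."""
    p, q = np.asarray(p, dtype=float), np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("probability surfaces differ in size")
    return float(1.0 - 0.5 * np.abs(p - q).sum())


def hellinger_i(p: np.ndarray, q: np.ndarray) -> float:
    """I = 1 − ½ Σ(√p_i − √q_i)² for two probability vectors."""
    p, q = np.asarray(p, dtype=float), np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("probability surfaces differ in size")
    return float(1.0 - 0.5 * ((np.sqrt(p) - np.sqrt(q)) ** 2).sum())


def pairwise_overlap(a: SuitabilityMap, b: SuitabilityMap,
                     label_a: str = "a", label_b: str = "b") -> OverlapResult:
    """D and I between two maps over their shared valid support."""
    ok = _common_valid(a, b)
    p = normalize_suitability(a, ok)
    q = normalize_suitability(b, ok)
    return OverlapResult(label_a, label_b, schoeners_d(p, q),
                         hellinger_i(p, q), int(ok.sum()))


def overlap_matrix(maps: Mapping[str, SuitabilityMap],
                   metric: str = "schoener_d") -> pd.DataFrame:
    """All pairwise overlaps; symmetric with unit diagonal.

    ``metric`` selects ``"schoener_d"`` or ``"hellinger_i"``.
    """
    if len(maps) < 2:
        raise ValueError("need at least two maps for an overlap matrix")
    if metric not in ("schoener_d", "hellinger_i"):
        raise ValueError(f"unknown metric {metric!r}")
    names = list(maps)
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            res = pairwise_overlap(maps[a], maps[b], a, b)
            val = getattr(res, metric)
            out.loc[a, b] = out.loc[b, a] = val
    return out
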