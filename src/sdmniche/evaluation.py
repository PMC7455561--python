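"""Model evaluation, ensemble combination, importance and area estimation.

Presence/background models are evaluated with five metrics: AUC
(Mann–Whitney form, ties counted ½), sensitivity, specificity and the
true skill statistic (TSS = sensitivity + specificity − 1) at the
max-TSS threshold, and the continuous Boyce index — the Spearman rank
correlation between predicted-to-expected presence ratios and window
midpoint across moving suitability windows, the standard presence-only
calibration metric.  Because true absences do not exist in this design,
"specificity" is computed over background points used as pseudo-absences.

Member maps are combined into an ensemble by a cellwise weighted mean
(uniform weights by default, or TSS-weighted).  Variable importance is
permutation-based: one minus the Pearson correlation between predictions
on the intact table and on the table with one column permuted, averaged
over repeats.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from .occurrences import OccurrenceSet
from .raster import RasterGrid, SuitabilityMap

__all__ = [
    "EvaluationResult",
    "ImportanceResult",
    "split_train_test",
    "auc",
    "threshold_metrics",
    "boyce_index",
    "ensemble_combine",
    "variable_importance",
    "binarize_and_area",
]

logger = logging.getLogger(__name__)


@dataclass
class EvaluationResult:
    """The five metrics plus the threshold the binary metrics used."""

    auc: float
    sensitivity: float
    specificity: float
    tss: float
    boyce: float
    threshold: float

    def __post_init__(self) -> None:
        if abs(self.tss - (self.sensitivity + self.specificity - 1.0)) > 1e-9:
            raise ValueError("tss must equal sensitivity + specificity - 1")

    def to_dict(self) -> dict[str, float | None]:
        b = None if np.isnan(self.boyce) else self.boyce
        return {"auc": self.auc, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "tss": self.tss,
                "boyce": b, "threshold": self.threshold}


@dataclass
class ImportanceResult:
    """Permutation importance per predictor, in [0, 1]."""

    importance: dict[str, float]
    n_repeats: int
    rng_seed: int

    def ranked(self) -> list[str]:
        return sorted(self.importance, key=self.importance.get, reverse=True)


def split_train_test(occ: OccurrenceSet, train_fraction: float = 0.8,
                     rng_seed: int = 0) -> tuple[OccurrenceSet, OccurrenceSet]:
    """Random disjoint, exhaustive split; train size = round(n × fraction)."""
    n = len(occ)
    if n < 5:
        raise ValueError("need at least 5 records to split")
    n_train = int(round(n * train_fraction))
    if n_train < 1 or n_train >= n:
        raise ValueError(
            f"train_fraction {train_fraction} leaves an empty partition at n={n}")
    perm = np.random.default_rng(rng_seed).permutation(n)
    return occ.subset(np.sort(perm[:n_train])), occ.subset(np.sort(perm[n_train:]))


def auc(presence_scores: Sequence[float],
        background_scores: Sequence[float]) -> float:
    """Mann–Whitney AUC: P(presence score > background score), ties ½."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("both score lists must be non-empty")
    ranks = rankdata(np.concatenate([p, b]))
    u = ranks[:p.size].sum() - p.size * (p.size + 1) / 2.0
    return float(u / (p.size * b.size))


def threshold_metrics(presence_scores: Sequence[float],
                      background_scores: Sequence[float]
                      ) -> tuple[float, float, float, float]:
    """Max-TSS threshold scan over all candidate score values.

    Returns (threshold, sensitivity, specificity, tss).  Sensitivity is
    the fraction of presence scores ≥ threshold; specificity the fraction
    of background scores < threshold; ties in TSS resolve to the lowest
    threshold.
    """
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("both score lists must be non-empty")
    candidates = np.unique(np.concatenate([p, b]))
    best = None
    for t in candidates:
        sens = float((p >= t).mean())
        spec = float((b < t).mean())
        tss = sens + spec - 1.0
        if best is None or tss > best[3] + 1e-12:
            best = (float(t), sens, spec, tss)
    return best


def boyce_index(presence_scores: Sequence[float],
                landscape_scores: Sequence[float],
                n_windows: int = 101,
                window_width_fraction: float = 0.1) -> float:
    """Continuous Boyce index in [−1, 1].

    Moving windows of width ``window_width_fraction`` × score range slide
    across [min, max] of the landscape scores at ``n_windows`` positions.
    Per window, P is the fraction of presence scores inside and E the
    fraction of landscape scores inside; the index is the Spearman rank
    correlation between P/E and the window midpoint, over windows with
    E > 0.  Degenerate inputs (constant scores, < 3 usable windows, or a
    constant P/E profile) return 0 with a warning.
    """
    p = np.asarray(presence_scores, dtype=float)
    land = np.asarray(landscape_scores, dtype=float)
    if p.size < 10:
        raise ValueError("need at least 10 presence scores")
    if land.size < 100:
        raise ValueError("need at least 100 landscape scores")
    lo, hi = float(land.min()), float(land.max())
    if hi <= lo:
        warnings.warn("degenerate score range; Boyce index undefined, returning 0")
        return 0.0
    width = window_width_fraction * (hi - lo)
    mids = np.linspace(lo + width / 2, hi - width / 2, n_windows)
    f_vals, f_mids = [], []
    for m in mids:
        wlo, whi = m - width / 2, m + width / 2
        e = float(((land >= wlo) & (land <= whi)).mean())
        if e <= 0:
            continue
        pr = float(((p >= wlo) & (p <= whi)).mean())
        f_vals.append(pr / e)
        f_mids.append(m)
    if len(f_vals) < 3 or np.ptp(f_vals) == 0:
        warnings.warn("too few usable windows or constant P/E; returning 0")
        return 0.0
    rho, _ = spearmanr(f_vals, f_mids)
    return float(rho)


def evaluate_scores(presence_scores: Sequence[float],
                    background_scores: Sequence[float],
                    landscape_scores: Sequence[float] | None = None
                    ) -> EvaluationResult:
    """All five metrics in one shot; landscape defaults to the background.

    If too few presence scores exist for a meaningful Boyce index
    (fewer than 10), Boyce is reported as NaN with a warning rather than
    failing the whole evaluation.
    """
    thr, sens, spec, tss = threshold_metrics(presence_scores, background_scores)
    land = background_scores if landscape_scores is None else landscape_scores
    try:
        boyce = boyce_index(presence_scores, land)
    except ValueError as exc:
        warnings.warn(f"Boyce index not computable: {exc}")
        boyce = float("nan")
    return EvaluationResult(
        auc=auc(presence_scores, background_scores),
        sensitivity=sens, specificity=spec, tss=tss,
        boyce=boyce, threshold=thr)


def ensemble_combine(maps: Sequence[SuitabilityMap],
                     weights: Sequence[float] | str = "uniform",
                     evaluations: Sequence[EvaluationResult] | None = None
                     ) -> SuitabilityMap:
    """Cellwise weighted mean of aligned member maps.

    ``weights`` is ``"uniform"``, ``"tss"`` (member TSS clipped at 0 and
    renormalized; requires ``evaluations``) or an explicit sequence.
    """
    if not maps:
        raise ValueError("no member maps")
    ref = maps[0].grid
    for m in maps[1:]:
        if not m.grid.same_grid(ref):
            raise ValueError("member maps are not aligned")
    if isinstance(weights, str):
        if weights == "uniform":
            w = np.ones(len(maps))
        elif weights == "tss":
            if evaluations is None or len(evaluations) != len(maps):
                raise ValueError("tss weighting needs one evaluation per map")
            w = np.array([max(e.tss, 0.0) for e in evaluations])
        else:
            raise ValueError(f"unknown weighting rule {weights!r}")
    else:
        w = np.asarray(weights, dtype=float)
        if w.size != len(maps) or (w < 0).any():
            raise ValueError("weights must be non-negative, one per map")
    if w.sum() <= 0:
        raise ValueError("all ensemble weights are zero")
    w = w / w.sum()
    vals = sum(wi * np.where(ref.mask, 0.0, m.grid.values)
               for wi, m in zip(w, maps))
    vals = np.where(ref.mask, np.nan, vals)
    grid = RasterGrid(vals, ref.transform, ref.crs_kind, ref.mask.copy())
    return SuitabilityMap(grid, metadata={"weights": w.tolist()})


def variable_importance(predict_fn, data: pd.DataFrame, n_repeats: int = 10,
                        rng_seed: int = 0) -> ImportanceResult:
    """Permutation importance: 1 − cor(pred, pred with column permuted).

    ``predict_fn`` is any callable mapping a predictor table to scores —
    a fitted model's ``predict_table`` or an ensemble wrapper.  Repeats
    are averaged and the result clipped to [0, 1]; a model with constant
    predictions gets importance 0 everywhere with a warning.
    """
    if len(data) < 30:
        raise ValueError("need at least 30 rows for permutation importance")
    if hasattr(predict_fn, "predict_table"):
        predict_fn = predict_fn.predict_table
    base = np.asarray(predict_fn(data), dtype=float)
    rng = np.random.default_rng(rng_seed)
    out: dict[str, float] = {}
    if np.std(base) == 0:
        warnings.warn("constant predictions; importance undefined, reporting 0")
        return ImportanceResult({c: 0.0 for c in data.columns},
                                n_repeats, rng_seed)
    for col in data.columns:
        vals = []
        for _ in range(n_repeats):
            shuf = data.copy()
            shuf[col] = rng.permutation(shuf[col].to_numpy())
            pred = np.asarray(predict_fn(shuf), dtype=float)
            if np.std(pred) == 0:
                vals.append(1.0)
                continue
            r = np.corrcoef(base, pred)[0, 1]
            vals.append(1.0 - r)
        out[col] = float(np.clip(np.mean(vals), 0.0, 1.0))
    return ImportanceResult(out, n_repeats, rng_seed)


def binarize_and_area(suit: SuitabilityMap,
                      threshold: float) -> tuple[RasterGrid, float]:
    """Threshold a suitability map and sum the suitable area in km².

    Cells with suitability ≥ threshold count as suitable.  Projected
    grids contribute cell_size² per cell; geographic grids use the
    per-row cosine-corrected cell area on a sphere.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    g = suit.grid
    suitable = g.valid & (np.nan_to_num(g.values, nan=-1.0) >= threshold)
    row_area = g.cell_area_km2()
    area = float((suitable.sum(axis=1) * row_area).sum())
    binary = RasterGrid(np.where(g.mask, np.nan, suitable.astype(float)),
                        g.transform, g.crs_kind, g.mask.copy())
    suit.threshold = threshold
    suit.binary = binary
    return binary, area
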