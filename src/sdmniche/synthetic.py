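"""Virtual landscapes and virtual species with known response curves.

Real habitat-suitability studies rest on downloaded climate and terrain
rasters plus field occurrence records.  This module replaces both with
controlled synthetic counterparts so that every pipeline stage can be
validated against a known truth: spatially autocorrelated, cross-
correlated environmental fields rescaled to realistic ranges (annual
precipitation in mm, summer maximum temperature in °C, elevation in m),
and species whose suitability is an explicit function of those fields.

Environmental fields are smoothed Gaussian white noise mixed through the
matrix square root of a target correlation matrix; the rescaling to the
requested value range is affine, so the imposed cross-correlations are
preserved exactly in expectation.  Presences are drawn with probability
proportional to suitability (a "probabilistic" virtual species), which
preserves the suitability gradient that response-curve recovery needs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import ndimage

from .occurrences import OccurrenceSet
from .raster import PROJECTED, GridTransform, PredictorStack, RasterGrid, SuitabilityMap

__all__ = [
    "GaussianResponse",
    "LogisticResponse",
    "VirtualSpecies",
    "SyntheticScenario",
    "generate_env_stack",
    "suitability_surface",
    "sample_presences",
    "sample_background",
]


@dataclass(frozen=True)
class GaussianResponse:
    """Bell-shaped response: suitability = exp(-(x - optimum)² / (2 width²))."""

    optimum: float
    width: float

    def __post_init__(self) -> None:
        if not (self.width > 0):
            raise ValueError("gaussian response width must be > 0")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        z = (np.asarray(x, dtype=float) - self.optimum) / self.width
        return np.exp(-0.5 * z * z)


@dataclass(frozen=True)
class LogisticResponse:
    """Sigmoid response: suitability = 1 / (1 + exp(-rate (x - midpoint)))."""

    midpoint: float
    rate: float

    def __call__(self, x: np.ndarray) -> np.ndarray:
        z = self.rate * (np.asarray(x, dtype=float) - self.midpoint)
        return 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700)))


@dataclass
class VirtualSpecies:
    """A species defined by per-predictor response functions.

    ``combination`` is either ``"product"`` (suitabilities multiply — the
    species needs all conditions at once) or ``"geometric-mean"`` (a
    softer compromise).  Either way the combined suitability stays in
    [0, 1], and for all-gaussian responses under ``product`` it reaches
    exactly 1 where every predictor sits at its optimum.
    """

    responses: dict[str, GaussianResponse | LogisticResponse]
    combination: str = "product"
    prevalence_target: float | None = None

    def __post_init__(self) -> None:
        if self.combination not in ("product", "geometric-mean"):
            raise ValueError("combination must be 'product' or 'geometric-mean'")
        if not self.responses:
            raise ValueError("a virtual species needs at least one response")


@dataclass
class SyntheticScenario:
    """Recipe for a correlated environmental raster stack.

    ``ranges`` maps predictor names to the (min, max) value range the
    rescaled field should span; ``correlation`` is the target cross-
    correlation matrix of the fields in the same predictor order.
    Defaults mimic a mid-latitude mountain landscape on a 200×200 grid of
    1 km projected cells, so distances and areas in tests are exact.
    """

    shape: tuple[int, int] = (200, 200)
    ranges: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "bio5": (18.0, 48.0),        # max temp of warmest month, °C
        "bio6": (-12.0, 8.0),        # min temp of coldest month, °C
        "bio12": (50.0, 1200.0),     # annual precipitation, mm
        "bio18": (0.0, 300.0),       # precipitation of warmest quarter, mm
        "elevation": (0.0, 3500.0),  # m
    })
    correlation: np.ndarray | None = None
    rng_seed: int = 0
    cell_size: float = 1000.0        # metres
    origin: tuple[float, float] = (0.0, 0.0)   # (x_min, y_min), map units
    crs_kind: str = PROJECTED
    smooth_sigma: float = 8.0        # cells; spatial autocorrelation length

    def __post_init__(self) -> None:
        rows, cols = self.shape
        if rows < 50 or cols < 50:
            raise ValueError("scenario grid must be at least 50×50")
        n = len(self.ranges)
        if self.correlation is None:
            self.correlation = np.eye(n)
        self.correlation = np.asarray(self.correlation, dtype=float)
        if self.correlation.shape != (n, n):
            raise ValueError("correlation matrix shape does not match predictors")
        if not np.allclose(self.correlation, self.correlation.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.correlation), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have unit diagonal")
        w = np.linalg.eigvalsh(self.correlation)
        if w.min() < -1e-8:
            raise ValueError(
                "correlation matrix is not positive semi-definite "
                f"(min eigenvalue {w.min():.3g}); choose pairwise correlations "
                "that are jointly consistent")

    @property
    def names(self) -> list[str]:
        return list(self.ranges)

    @property
    def transform(self) -> GridTransform:
        x0, y0 = self.origin
        rows, _ = self.shape
        return GridTransform(x0, y0 + rows * self.cell_size, self.cell_size)


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float) -> np.ndarray:
    """Unit-variance spatially autocorrelated field from smoothed white noise."""
    z = rng.standard_normal(shape)
    if sigma > 0:
        z = ndimage.gaussian_filter(z, sigma, mode="reflect")
    z -= z.mean()
    sd = z.std()
    return z / sd if sd > 0 else z


def generate_env_stack(scenario: SyntheticScenario) -> PredictorStack:
    """Generate the correlated predictor stack a scenario describes.

    Independent smoothed fields are mixed through the symmetric square
    root of the target correlation matrix, then each mixed field is
    affinely rescaled to its predictor's (min, max) range.  The result is
    deterministic for a fixed ``rng_seed``.
    """
    rng = np.random.default_rng(scenario.rng_seed)
    names = scenario.names
    n = len(names)
    fields = np.stack([_smooth_field(rng, scenario.shape, scenario.smooth_sigma)
                       for _ in range(n)])
    # Smoothing leaves few effective degrees of freedom per field, so the
    # empirical cross-correlation of independent smoothed fields can drift
    # far from zero.  Whiten empirically before mixing so the imposed
    # correlations hold exactly over the generated cells.
    flat = fields.reshape(n, -1)
    flat -= flat.mean(axis=1, keepdims=True)
    emp = np.corrcoef(flat)
    we, ve = np.linalg.eigh(emp)
    white = ve @ np.diag(1.0 / np.sqrt(np.clip(we, 1e-12, None))) @ ve.T
    flat = white @ flat
    # matrix square root via eigendecomposition (PSD guaranteed by scenario)
    w, v = np.linalg.eigh(scenario.correlation)
    root = v @ np.diag(np.sqrt(np.clip(w, 0, None))) @ v.T
    mixed = (root @ flat).reshape(n, *scenario.shape)
    tr = scenario.transform
    layers: dict[str, RasterGrid] = {}
    for i, name in enumerate(names):
        f = mixed[i]
        lo, hi = scenario.ranges[name]
        fmin, fmax = f.min(), f.max()
        if fmax > fmin:
            f = lo + (f - fmin) * (hi - lo) / (fmax - fmin)
        else:
            f = np.full_like(f, (lo + hi) / 2.0)
        layers[name] = RasterGrid(f, tr, scenario.crs_kind)
    return PredictorStack(layers)


def suitability_surface(species: VirtualSpecies,
                        stack: PredictorStack) -> SuitabilityMap:
    """Evaluate the species' combined response on every stack cell."""
    missing = [n for n in species.responses if n not in stack.layers]
    if missing:
        raise KeyError(f"predictors missing from stack: {missing}")
    parts = [resp(stack[name].values) for name, resp in species.responses.items()]
    prod = np.prod(np.stack(parts), axis=0)
    if species.combination == "geometric-mean":
        prod = prod ** (1.0 / len(parts))
    vals = np.where(stack.mask, np.nan, np.clip(prod, 0.0, 1.0))
    return SuitabilityMap(RasterGrid(vals, stack.transform, stack.crs_kind,
                                     stack.mask.copy()))


def sample_presences(suit: SuitabilityMap, n: int, rng_seed: int,
                     species_label: str = "virtual") -> OccurrenceSet:
    """Draw presence points with cell probability proportional to suitability.

    Points are jittered uniformly within their cell, so coordinates are
    continuous.  Sampling is with replacement (several presences may fall
    in one cell, as with real observations) and reproducible by seed.
    """
    if n < 1:
        raise ValueError("need n >= 1 presences")
    g = suit.grid
    w = np.where(g.valid, np.nan_to_num(g.values, nan=0.0), 0.0).ravel()
    total = w.sum()
    if total <= 0:
        raise ValueError("suitability is zero everywhere; cannot sample presences")
    rng = np.random.default_rng(rng_seed)
    flat = rng.choice(w.size, size=n, replace=True, p=w / total)
    rows, cols = np.unravel_index(flat, g.shape)
    cs = g.transform.cell_size
    x = g.transform.x_min + (cols + rng.random(n)) * cs
    y = g.transform.y_max - (rows + rng.random(n)) * cs
    return OccurrenceSet(np.column_stack([x, y]), species_label=species_label,
                         stage="raw", crs_kind=g.crs_kind)


def sample_background(stack: PredictorStack, n: int, rng_seed: int,
                      exclude: OccurrenceSet | None = None,
                      species_label: str = "background") -> OccurrenceSet:
    """Draw background cells uniformly without replacement from valid cells.

    Cells containing an excluded occurrence are never drawn.  Returned
    points sit at cell centers.
    """
    g = stack.grid
    ok = g.valid.copy()
    if exclude is not None and len(exclude) > 0:
        r, c = g.transform.index(exclude.xy[:, 0], exclude.xy[:, 1], g.shape)
        inside = (r >= 0) & (c >= 0)
        ok[r[inside], c[inside]] = False
    avail = np.flatnonzero(ok.ravel())
    if n > avail.size:
        raise ValueError(
            f"requested {n} background cells but only {avail.size} are available")
    rng = np.random.default_rng(rng_seed)
    chosen = rng.choice(avail, size=n, replace=False)
    rows, cols = np.unravel_index(chosen, g.shape)
    cs = g.transform.cell_size
    x = g.transform.x_min + (cols + 0.5) * cs
    y = g.transform.y_max - (rows + 0.5) * cs
    return OccurrenceSet(np.column_stack([x, y]), species_label=species_label,
                         stage="raw", crs_kind=g.crs_kind)
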