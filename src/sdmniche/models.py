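"""Presence/background suitability models behind one fit/predict contract.

Five algorithms are supported, all mapping a table of predictor values to
habitat suitability in [0, 1]:

``glm``
    Logistic regression of presence (1) vs background (0) with linear and
    quadratic terms per predictor — the quadratic terms let the model
    express unimodal (niche-shaped) responses.
``gam``
    Logistic additive model on cubic B-spline bases, 4 effective degrees
    of freedom per predictor (one interior knot at the training median).
``gbm``
    Stochastic gradient-boosted trees on the Bernoulli deviance.
``maxent``
    An L1-regularized exponential (Gibbs) model over linear, quadratic,
    product and hinge features, normalized over the background sample —
    the presence/background maximum-entropy formulation.  Its raw output
    is a probability distribution over background cells; predictions are
    rescaled to [0, 1] with the standard complementary log-log transform
    anchored at the entropy of that distribution.
``rf``
    Random-forest class probability with balanced per-tree class
    resampling.

Predictors are standardized internally (training mean/SD over presences
plus background) before any feature construction, so coefficients and
regularization are scale-free.  Constant predictors are dropped with a
warning.  All stochastic fits are seeded; prediction after fitting is
deterministic.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from scipy.interpolate import BSpline

from .raster import PredictorStack, RasterGrid, SuitabilityMap

__all__ = [
    "ALGORITHMS",
    "ModelSpec",
    "FittedModel",
    "ResponseCurve",
    "fit_model",
    "predict_suitability",
    "response_curve",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

ALGORITHMS = ("glm", "gam", "gbm", "maxent", "rf")

DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "glm": {},
    "gam": {"df": 4},
    "gbm": {"n_trees": 2000, "learning_rate": 0.01, "interaction_depth": 3,
            "bag_fraction": 0.5},
    "maxent": {"reg_multiplier": 1.0, "hinge_knots": 5,
               "feature_threshold": 80},
    "rf": {"n_trees": 500},
}


@dataclass
class ModelSpec:
    """Algorithm choice plus hyperparameters and a seed."""

    algorithm: str
    hyperparameters: dict = field(default_factory=dict)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}")
        defaults = DEFAULT_HYPERPARAMETERS[self.algorithm]
        unknown = set(self.hyperparameters) - set(defaults)
        if unknown:
            raise ValueError(
                f"unknown {self.algorithm} hyperparameters: {sorted(unknown)}")
        self.hyperparameters = {**defaults, **self.hyperparameters}


@dataclass
class ResponseCurve:
    """Suitability along one predictor, others held at their training mean."""

    predictor: str
    grid: np.ndarray
    suitability: np.ndarray
    held_constant: dict[str, float]

    @property
    def peak(self) -> float:
        """Predictor value at maximum suitability."""
        return float(self.grid[int(np.argmax(self.suitability))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({self.predictor: self.grid,
                             "suitability": self.suitability})


# ---------------------------------------------------------------------------
# internal feature builders

def _spline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Cubic B-spline design matrix (first column dropped for identifiability)."""
    t = np.r_[[knots[0]] * 4, knots[1:-1], [knots[-1]] * 4]
    xc = np.clip(x, knots[0], knots[-1])
    dm = BSpline.design_matrix(xc, t, 3).toarray()
    return dm[:, 1:]


def _hinge_features(x: np.ndarray, knots: np.ndarray,
                    lo: float, hi: float) -> list[np.ndarray]:
    """Forward and reverse hinge features, scaled to [0, 1] over [lo, hi]."""
    feats = []
    for k in knots:
        if hi > k:
            feats.append(np.clip((x - k) / (hi - k), 0, None))
        if k > lo:
            feats.append(np.clip((k - x) / (k - lo), 0, None))
    return feats


class _MaxentCore:
    """Gibbs density over background with L1-penalized likelihood.

    Maximizes  mean_presence(η) − log mean_background(exp η) − α Σ|λ|
    with η = λ·f(x); the fitted density q_i = exp(η_i)/Σ_bg exp(η_j)
    sums to one over the background sample by construction.
    """

    def __init__(self, reg_multiplier: float, hinge_knots: int,
                 feature_threshold: int) -> None:
        self.reg = reg_multiplier
        self.n_hinge = hinge_knots
        self.feature_threshold = feature_threshold

    def _build_features(self, Z: np.ndarray) -> np.ndarray:
        cols = [Z, Z ** 2]
        if self.use_complex:
            p = Z.shape[1]
            prods = [Z[:, i] * Z[:, j] for i in range(p) for j in range(i + 1, p)]
            if prods:
                cols.append(np.column_stack(prods))
            hinges = []
            for j in range(p):
                lo, hi = self.z_range[:, j]
                hinges.extend(_hinge_features(Z[:, j], self.hinge_grid[:, j], lo, hi))
            if hinges:
                cols.append(np.column_stack(hinges))
        F = np.hstack([c if c.ndim == 2 else c[:, None] for c in cols])
        return (F - self.f_mean) / self.f_sd

    def fit(self, Zp: np.ndarray, Zb: np.ndarray) -> None:
        n_pres = Zp.shape[0]
        self.use_complex = n_pres >= self.feature_threshold
        self.z_range = np.vstack([Zb.min(axis=0), Zb.max(axis=0)])
        qs = np.linspace(0.1, 0.9, self.n_hinge)
        self.hinge_grid = np.quantile(Zb, qs, axis=0)
        # feature standardization over background
        self.f_mean = 0.0
        self.f_sd = 1.0
        Fb_raw = self._build_features(Zb)
        self.f_mean = Fb_raw.mean(axis=0)
        sd = Fb_raw.std(axis=0)
        self.f_sd = np.where(sd > 0, sd, 1.0)
        Fb = self._build_features(Zb)
        Fp = self._build_features(Zp)
        m = Fb.shape[1]
        alpha = self.reg * np.sqrt(np.log(max(n_pres, 2)) / n_pres)
        fp_mean = Fp.mean(axis=0)

        def objective(theta):
            lam = theta[:m] - theta[m:]
            eta_b = Fb @ lam
            lz = logsumexp(eta_b)
            q = np.exp(eta_b - lz)
            nll = -(fp_mean @ lam) + lz - np.log(Fb.shape[0]) + alpha * theta.sum()
            grad_lam = -fp_mean + Fb.T @ q
            grad = np.concatenate([grad_lam + alpha, -grad_lam + alpha])
            return nll, grad

        res = minimize(objective, np.zeros(2 * m), jac=True, method="L-BFGS-B",
                       bounds=[(0, None)] * (2 * m),
                       options={"maxiter": 500, "ftol": 1e-10})
        self.converged = bool(res.success)
        if not res.success:
            logger.warning("maxent optimizer stopped early: %s", res.message)
        self.lam = res.x[:m] - res.x[m:]
        eta_b = Fb @ self.lam
        self.log_z = float(logsumexp(eta_b))
        q = np.exp(eta_b - self.log_z)
        self.entropy = float(-(q * np.log(np.clip(q, 1e-300, None))).sum())

    def background_density(self, Zb: np.ndarray) -> np.ndarray:
        """The fitted distribution over a background sample (sums to 1)."""
        eta = self._build_features(Zb) @ self.lam
        return np.exp(eta - logsumexp(eta))

    def predict(self, Z: np.ndarray) -> np.ndarray:
        eta = self._build_features(Z) @ self.lam
        # q relative to the training background normalizer
        log_q = eta - self.log_z
        # complementary log-log output anchored at the background entropy:
        # uniform-density cells map to 1 − e^{−1} ≈ 0.63
        return 1.0 - np.exp(-np.exp(self.entropy + log_q))


@dataclass
class FittedModel:
    """Any of the five algorithms, fitted; predicts suitability in [0, 1]."""

    spec: ModelSpec
    predictors: list[str]
    training_range: dict[str, tuple[float, float]]
    n_presence: int
    n_background: int
    center: np.ndarray = field(repr=False, default=None)
    scale: np.ndarray = field(repr=False, default=None)
    training_mean: dict[str, float] = field(default_factory=dict)
    _impl: object = field(repr=False, default=None)
    usable: bool = True
    notes: list[str] = field(default_factory=list)

    def predict_table(self, table: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Suitability for each row of a predictor-value table."""
        if isinstance(table, pd.DataFrame):
            missing = [p for p in self.predictors if p not in table.columns]
            if missing:
                raise KeyError(f"missing predictors: {missing}")
            X = table[self.predictors].to_numpy(dtype=float)
        else:
            X = np.asarray(table, dtype=float)
            if X.shape[1] != len(self.predictors):
                raise ValueError("column count does not match model predictors")
        Z = (X - self.center) / self.scale
        alg = self.spec.algorithm
        if alg == "glm":
            p = self._impl.predict_proba(np.hstack([Z, Z ** 2]))[:, 1]
        elif alg == "gam":
            B = np.hstack([_spline_basis(Z[:, j], self._impl["knots"][j])
                           for j in range(Z.shape[1])])
            p = self._impl["clf"].predict_proba(B)[:, 1]
        elif alg in ("gbm", "rf"):
            p = self._impl.predict_proba(Z)[:, 1]
        elif alg == "maxent":
            p = self._impl.predict(Z)
        else:  # pragma: no cover
            raise AssertionError(alg)
        return np.clip(p, 0.0, 1.0)


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    return center, scale


def fit_model(spec: ModelSpec, presences: pd.DataFrame,
              background: pd.DataFrame) -> FittedModel:
    """Fit one algorithm on presence (1) vs background (0) predictor tables."""
    if list(presences.columns) != list(background.columns):
        raise ValueError("presence and background tables must share columns")
    if len(presences) < 10 or len(background) < 10:
        raise ValueError("need at least 10 presence and 10 background rows")
    cols = list(presences.columns)
    keep = [c for c in cols
            if presences[c].nunique() > 1 or background[c].nunique() > 1]
    dropped = sorted(set(cols) - set(keep))
    if dropped:
        logger.warning("dropping constant predictors: %s", dropped)
    if not keep:
        raise ValueError("all predictors are constant")
    Xp = presences[keep].to_numpy(dtype=float)
    Xb = background[keep].to_numpy(dtype=float)
    Xall = np.vstack([Xp, Xb])
    center, scale = _standardize(Xall)
    Zp, Zb = (Xp - center) / scale, (Xb - center) / scale
    Zall = np.vstack([Zp, Zb])
    y = np.r_[np.ones(len(Zp)), np.zeros(len(Zb))]
    hp = spec.hyperparameters
    notes = [f"dropped constant predictor {c}" for c in dropped]
    usable = True

    if spec.algorithm == "glm":
        D = np.hstack([Zall, Zall ** 2])
        impl = LogisticRegression(C=np.inf, max_iter=2000, tol=1e-8)
        import warnings
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            impl.fit(D, y)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            notes.append("glm did not converge unpenalized; ridge fallback")
            logger.warning("glm non-convergence; refitting with small ridge")
            impl = LogisticRegression(C=100.0, max_iter=5000)
            impl.fit(D, y)
    elif spec.algorithm == "gam":
        df = int(hp["df"])
        knots = []
        B_parts = []
        for j in range(Zall.shape[1]):
            zj = Zall[:, j]
            # cubic basis: df - 3 interior knots give df basis functions
            # after dropping one column for identifiability
            interior = np.quantile(zj, np.linspace(0, 1, df - 1)[1:-1])
            k = np.r_[zj.min(), interior, zj.max()]
            knots.append(np.unique(k))
            B_parts.append(_spline_basis(zj, knots[-1]))
        B = np.hstack(B_parts)
        clf = LogisticRegression(C=1000.0, max_iter=5000)
        clf.fit(B, y)
        impl = {"clf": clf, "knots": knots}
    elif spec.algorithm == "gbm":
        impl = GradientBoostingClassifier(
            n_estimators=int(hp["n_trees"]), learning_rate=hp["learning_rate"],
            max_depth=int(hp["interaction_depth"]), subsample=hp["bag_fraction"],
            random_state=spec.rng_seed)
        impl.fit(Zall, y)
    elif spec.algorithm == "rf":
        impl = RandomForestClassifier(
            n_estimators=int(hp["n_trees"]), random_state=spec.rng_seed,
            class_weight="balanced_subsample", n_jobs=1)
        impl.fit(Zall, y)
    elif spec.algorithm == "maxent":
        impl = _MaxentCore(hp["reg_multiplier"], int(hp["hinge_knots"]),
                           int(hp["feature_threshold"]))
        impl.fit(Zp, Zb)
        if not impl.converged:
            notes.append("maxent optimizer stopped before convergence")

    rng = {c: (float(Xall[:, i].min()), float(Xall[:, i].max()))
           for i, c in enumerate(keep)}
    means = {c: float(Xall[:, i].mean()) for i, c in enumerate(keep)}
    return FittedModel(spec=spec, predictors=keep, training_range=rng,
                       n_presence=len(Zp), n_background=len(Zb),
                       center=center, scale=scale, training_mean=means,
                       _impl=impl, usable=usable, notes=notes)


def predict_suitability(model: FittedModel,
                        stack: PredictorStack) -> SuitabilityMap:
    """Predict suitability on every valid stack cell; nodata propagates."""
    missing = [p for p in model.predictors if p not in stack.layers]
    if missing:
        raise KeyError(f"stack lacks predictor layers: {missing}")
    ok = stack.grid.valid
    X = np.column_stack([stack[p].values[ok] for p in model.predictors])
    pred = model.predict_table(X)
    vals = np.full(stack.shape, np.nan)
    vals[ok] = pred
    grid = RasterGrid(vals, stack.transform, stack.crs_kind, stack.mask.copy())
    return SuitabilityMap(grid, metadata={"algorithm": model.spec.algorithm})


def response_curve(model: FittedModel, predictor: str,
                   grid_size: int = 100) -> ResponseCurve:
    """Vary one predictor across its training range, others at their mean."""
    if predictor not in model.predictors:
        raise KeyError(f"{predictor!r} is not a model predictor")
    lo, hi = model.training_range[predictor]
    grid = np.linspace(lo, hi, grid_size)
    held = {p: model.training_mean[p] for p in model.predictors if p != predictor}
    table = pd.DataFrame({p: np.full(grid_size, held[p]) for p in held})
    table[predictor] = grid
    suit = model.predict_table(table[model.predictors])
    return ResponseCurve(predictor=predictor, grid=grid, suitability=suit,
                         held_constant=held)


# ---------------------------------------------------------------------------
# serialization

_ARCHIVE_VERSION = 1


def save_model(model: FittedModel, path: str | Path) -> None:
    """Serialize a fitted model (versioned pickle archive)."""
    with open(path, "wb") as fh:
        pickle.dump({"version": _ARCHIVE_VERSION, "model": model}, fh)


def load_model(path: str | Path) -> FittedModel:
    with open(path, "rb") as fh:
        blob = pickle.load(fh)
    if blob.get("version") != _ARCHIVE_VERSION:
        raise ValueError(f"unsupported model archive version: {blob.get('version')}")
    return blob["model"]
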