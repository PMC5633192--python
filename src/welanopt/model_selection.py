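"""Hyperparameter selection for the SVR surrogate.

The penalty parameter ``c`` (= C) and kernel parameter ``g`` (= 1/sigma^2) are
chosen on a log2-spaced grid by minimizing CVmse, the mean squared error of
held-out predictions under k-fold cross-validation (5-fold by default).
Model accuracy is reported as the square of the Pearson correlation between
predictions and targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .svr import SVRConfig, fit

__all__ = [
    "GridSpec",
    "GridResult",
    "kfold_indices",
    "cv_mse",
    "grid_search",
    "r_squared",
]

FitPredict = Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]


def _default_grid(lo: int, hi: int) -> tuple[float, ...]:
    return tuple(float(2.0**p) for p in range(lo, hi + 1))


@dataclass(frozen=True)
class GridSpec:
    """Log2-spaced candidate grid for (c, g) and the CV folding.

    Defaults span c = 2^-2 .. 2^10 and g = 2^-8 .. 2^4 with step 1 in log2.
    """

    c_values: tuple[float, ...] = field(default_factory=lambda: _default_grid(-2, 10))
    g_values: tuple[float, ...] = field(default_factory=lambda: _default_grid(-8, 4))
    k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.c_values) == 0 or len(self.g_values) == 0:
            raise ValueError("grids must be non-empty")
        if any(v <= 0 for v in self.c_values) or any(v <= 0 for v in self.g_values):
            raise ValueError("grid values must be positive")
        if self.k < 2:
            raise ValueError(f"fold count k must be >= 2, got {self.k}")


@dataclass
class GridResult:
    """CVmse per grid cell and the winning (c, g)."""

    cvmse: np.ndarray  # shape (len(c_values), len(g_values))
    c_values: tuple[float, ...]
    g_values: tuple[float, ...]
    best_c: float
    best_g: float
    best_cvmse: float
    fold_errors: np.ndarray  # per-fold MSE at the best cell

    @property
    def best_config(self) -> SVRConfig:
        return SVRConfig.from_c_g(self.best_c, self.best_g)

    def to_frame(self) -> pd.DataFrame:
        """One row per grid cell (for CSV export / contour plotting)."""
        rows = [
            {
                "c": c,
                "g": g,
                "log2_c": np.log2(c),
                "log2_g": np.log2(g),
                "cvmse": self.cvmse[i, j],
            }
            for i, c in enumerate(self.c_values)
            for j, g in enumerate(self.g_values)
        ]
        return pd.DataFrame(rows)


def kfold_indices(n: int, k: int, seed: int = 0) -> np.ndarray:
    """Assign each of n indices to one of k folds, sizes differing by <= 1."""
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    # first n % k folds get one extra element
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    start = 0
    for f, size in enumerate(sizes):
        folds[perm[start : start + size]] = f
        start += size
    return folds


def _svr_fit_predict(config: SVRConfig) -> FitPredict:
    def fp(X_train: np.ndarray, y_train: np.ndarray, X_test: np.ndarray) -> np.ndarray:
        model = fit(X_train, y_train, config)
        return np.atleast_1d(model.predict(X_test))

    return fp


def cv_mse(
    X: np.ndarray,
    y: np.ndarray,
    folds: np.ndarray,
    config: SVRConfig | None = None,
    fit_predict: FitPredict | None = None,
) -> float:
    """Mean over all held-out points of squared (prediction - target).

    ``fit_predict`` may replace the SVR trainer (used by tests with stub
    predictors); exactly one of ``config`` / ``fit_predict`` is required.
    """
    if (config is None) == (fit_predict is None):
        raise ValueError("pass exactly one of config or fit_predict")
    if fit_predict is None:
        fit_predict = _svr_fit_predict(config)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    folds = np.asarray(folds)
    sq = np.empty_like(y)
    for f in np.unique(folds):
        held = folds == f
        if (~held).sum() < 2:
            raise ValueError(f"fold {f}: fewer than 2 training points remain")
        pred = fit_predict(X[~held], y[~held], X[held])
        sq[held] = (pred - y[held]) ** 2
    return float(sq.mean())


def grid_search(X: np.ndarray, y: np.ndarray, grid: GridSpec, epsilon: float = 0.01) -> GridResult:
    """Evaluate CVmse at every (c, g) cell with shared folds; return the argmin.

    Ties are broken toward the smallest c, then the smallest g (the smoother
    model), independent of grid enumeration order.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    folds = kfold_indices(len(y), grid.k, grid.seed)
    cs = tuple(sorted(grid.c_values))
    gs = tuple(sorted(grid.g_values))
    cvmse = np.empty((len(cs), len(gs)))
    for i, c in enumerate(cs):
        for j, g in enumerate(gs):
            cfg = SVRConfig.from_c_g(c, g, epsilon=epsilon)
            cvmse[i, j] = cv_mse(X, y, folds, config=cfg)
    # ascending enumeration + strict < implements the tie rule
    best_i, best_j, best = 0, 0, np.inf
    for i in range(len(cs)):
        for j in range(len(gs)):
            if cvmse[i, j] < best:
                best_i, best_j, best = i, j, cvmse[i, j]
    # per-fold errors at the winning cell
    best_cfg = SVRConfig.from_c_g(cs[best_i], gs[best_j], epsilon=epsilon)
    fp = _svr_fit_predict(best_cfg)
    errs = []
    for f in np.unique(folds):
        held = folds == f
        pred = fp(X[~held], y[~held], X[held])
        errs.append(float(np.mean((pred - y[held]) ** 2)))
    return GridResult(
        cvmse=cvmse,
        c_values=cs,
        g_values=gs,
        best_c=cs[best_i],
        best_g=gs[best_j],
        best_cvmse=float(best),
        fold_errors=np.array(errs),
    )


def r_squared(predictions: np.ndarray, targets: np.ndarray) -> float:
    """Square of the Pearson correlation between predictions and targets.

    Affine-invariant in either argument, so it gives the same accuracy on the
    normalized and the raw g/L scale.  Constant inputs have no defined
    correlation and raise.
    """
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(targets, dtype=float)
    if p.shape != t.shape or p.ndim != 1:
        raise ValueError("predictions and targets must be 1-D and equal length")
    if len(p) < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(p) == 0 or np.ptp(t) == 0:
        raise ValueError("correlation undefined for constant predictions or targets")
    r = stats.pearsonr(p, t).statistic
    return float(r * r)
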