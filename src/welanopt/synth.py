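"""Synthetic fermentation-surface generator.

The study's full 67-record dataset was never published (only 25 records are
printed), so this module emulates it: condition vectors drawn uniformly inside
the wide search bounds, with yield generated from a known smooth response
surface with a single interior optimum plus additive Gaussian noise,

    y = max(0, y* - sum_j w_j (x_j - x*_j)^2 + noise).

Because the generator retains its ground truth (x*, y*), recovery tests can
measure how well the surrogate + GA pipeline relocates the true optimum.
A Gaussian-peak surface (same curvature at the optimum) is available as an
alternative shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aga import Bounds, WIDE_BOUNDS, N_GENES
from .data_prep import CONDITION_COLUMNS, PRODUCTION_COLUMN

__all__ = ["SyntheticSurfaceSpec", "synth_generate", "default_spec"]

#: Default true optimum: an interior point near the high-yield region of the
#: real study, strictly inside every wide bound.
DEFAULT_X_STAR = (55.0, 2.9, 5.2, 0.3, 50.0, 7.0, 32.5, 177.0, 5.0)

#: Default peak yield (g/L), matching the maximum production implied by the
#: printed normalized table (~42.4 g/L).
DEFAULT_Y_STAR = 42.0

#: Yield drop (g/L) at the farthest bound edge of each variable; sets the
#: default curvature weights.  At this value the generated low/mid/high yield
#: mix is close to the real study's 8/39/20 of 67.
DEFAULT_EDGE_DROP = 10.0


def _default_weights(bounds: Bounds, x_star: np.ndarray, edge_drop: float) -> np.ndarray:
    reach = np.maximum(bounds.hi_array - x_star, x_star - bounds.lo_array)
    return edge_drop / reach**2


@dataclass(frozen=True)
class SyntheticSurfaceSpec:
    """Ground-truth surface and sampling plan for synthetic records."""

    x_star: tuple[float, ...] = DEFAULT_X_STAR
    y_star: float = DEFAULT_Y_STAR
    weights: tuple[float, ...] | None = None  # default: edge-drop rule
    noise_sd: float = 0.5
    n: int = 67
    seed: int = 0
    bounds: Bounds = WIDE_BOUNDS
    shape: str = "quadratic"  # or "gaussian"

    def __post_init__(self) -> None:
        xs = np.asarray(self.x_star, dtype=float)
        if xs.shape != (N_GENES,):
            raise ValueError(f"x_star must have {N_GENES} components")
        if not (np.all(xs > self.bounds.lo_array) and np.all(xs < self.bounds.hi_array)):
            raise ValueError("x_star must lie strictly inside the bounds")
        if self.y_star <= 0:
            raise ValueError(f"peak yield y_star must be positive, got {self.y_star}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.n < 1:
            raise ValueError(f"sample count n must be >= 1, got {self.n}")
        if self.shape not in ("quadratic", "gaussian"):
            raise ValueError(f"unknown surface shape {self.shape!r}")
        if self.weights is not None and len(self.weights) != N_GENES:
            raise ValueError(f"weights must have {N_GENES} components")

    @property
    def x_star_array(self) -> np.ndarray:
        return np.asarray(self.x_star, dtype=float)

    @property
    def weight_array(self) -> np.ndarray:
        if self.weights is not None:
            return np.asarray(self.weights, dtype=float)
        return _default_weights(self.bounds, self.x_star_array, DEFAULT_EDGE_DROP)

    def true_yield(self, X: np.ndarray) -> np.ndarray:
        """Noise-free surface value at condition vector(s) X."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        q = np.sum(self.weight_array * (X - self.x_star_array) ** 2, axis=1)
        if self.shape == "gaussian":
            y = self.y_star * np.exp(-q / self.y_star)
        else:
            y = self.y_star - q
        return np.maximum(y, 0.0)


def synth_generate(spec: SyntheticSurfaceSpec) -> pd.DataFrame:
    """Draw ``spec.n`` records uniformly inside the bounds with noisy yields."""
    rng = np.random.default_rng(spec.seed)
    X = rng.uniform(
        spec.bounds.lo_array, spec.bounds.hi_array, size=(spec.n, N_GENES)
    )
    y = spec.true_yield(X)
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=spec.n)
    y = np.maximum(y, 0.0)
    table = pd.DataFrame(X, columns=list(CONDITION_COLUMNS))
    table[PRODUCTION_COLUMN] = y
    return table


def default_spec(**overrides) -> SyntheticSurfaceSpec:
    """The study-scale synthetic dataset spec (n=67, noise 0.5 g/L)."""
    return SyntheticSurfaceSpec(**overrides)
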