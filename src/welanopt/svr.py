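"""Epsilon-support-vector regression with a Gaussian RBF kernel.

The regression function is the kernel expansion

    f(x) = sum_{i in SV} (alpha_i - alpha_i*) K(x_i, x) + b,
    K(x_i, x_j) = exp(-||x_i - x_j||^2 / sigma^2),

obtained by solving the dual quadratic program

    min_{a, a*}  1/2 sum_ij (a_i - a_i*)(a_j - a_j*) K_ij
                 + eps * sum_i (a_i + a_i*) - sum_i y_i (a_i - a_i*)
    s.t.         sum_i (a_i - a_i*) = 0,   0 <= a_i, a_i* <= C.

Note the kernel denominator is ``sigma^2`` (not the also-common ``2 sigma^2``);
the grid-search parameter ``g`` relates to it as ``g = 1 / sigma^2``.

The solver works on the net coefficients ``beta_i = alpha_i - alpha_i*``
(complementarity ``alpha_i * alpha_i* = 0`` makes the two representations
equivalent: ``alpha_i = max(beta_i, 0)``, ``alpha_i* = max(-beta_i, 0)``).
It performs SMO-style maximal-violating-pair updates: at each step the pair of
points whose KKT intervals for the bias are most inconsistent is selected and
the exact two-variable subproblem — a piecewise quadratic in one scalar after
eliminating the equality constraint — is solved in closed form.  Convergence
is declared when the worst KKT violation drops below ``kkt_tolerance``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SVRConfig",
    "DualSolution",
    "SurrogateModel",
    "rbf_kernel",
    "gram_matrix",
    "solve_dual",
    "dual_objective",
    "compute_bias",
    "fit",
]

#: Net coefficients smaller than this (relative to C) are treated as zero.
SV_THRESHOLD = 1e-8


@dataclass(frozen=True)
class SVRConfig:
    """Hyperparameters of the epsilon-SVR.

    C > 0 is the penalty weight on tube violations, ``epsilon`` the half-width
    of the insensitive tube on the (normalized) target scale, ``sigma`` the
    RBF kernel width on the (normalized) input scale.
    """

    C: float = 1.0
    epsilon: float = 0.01
    sigma: float = 1.0
    kkt_tolerance: float = 1e-6
    max_passes: int = 200_000

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError(f"C must be positive, got {self.C}")
        if self.epsilon < 0:
            raise ValueError(f"epsilon must be non-negative, got {self.epsilon}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.kkt_tolerance <= 0:
            raise ValueError("kkt_tolerance must be positive")

    @property
    def gamma(self) -> float:
        """Grid-search kernel parameter g = 1 / sigma^2."""
        return 1.0 / self.sigma**2

    @classmethod
    def from_c_g(cls, c: float, g: float, **kwargs) -> "SVRConfig":
        """Build from the grid-search parameterization (c, g) = (C, 1/sigma^2)."""
        if g <= 0:
            raise ValueError(f"kernel parameter g must be positive, got {g}")
        return cls(C=c, sigma=1.0 / np.sqrt(g), **kwargs)


def rbf_kernel(xi: np.ndarray, xj: np.ndarray, sigma: float) -> float:
    """Gaussian RBF kernel value exp(-||xi - xj||^2 / sigma^2)."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    xi = np.asarray(xi, dtype=float)
    xj = np.asarray(xj, dtype=float)
    if xi.shape != xj.shape:
        raise ValueError(f"shape mismatch: {xi.shape} vs {xj.shape}")
    d2 = float(np.sum((xi - xj) ** 2))
    return float(np.exp(-d2 / sigma**2))


def gram_matrix(points: np.ndarray, sigma: float, other: np.ndarray | None = None) -> np.ndarray:
    """Kernel matrix K[i, j] = exp(-||p_i - q_j||^2 / sigma^2).

    With ``other=None`` returns the symmetric unit-diagonal Gram matrix of
    ``points`` against itself.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    P = np.atleast_2d(np.asarray(points, dtype=float))
    Q = P if other is None else np.atleast_2d(np.asarray(other, dtype=float))
    if P.shape[1] != Q.shape[1]:
        raise ValueError(f"dimension mismatch: {P.shape[1]} vs {Q.shape[1]}")
    d2 = (
        np.sum(P**2, axis=1)[:, None]
        + np.sum(Q**2, axis=1)[None, :]
        - 2.0 * P @ Q.T
    )
    np.maximum(d2, 0.0, out=d2)
    K = np.exp(-d2 / sigma**2)
    if other is None:
        np.fill_diagonal(K, 1.0)
        K = 0.5 * (K + K.T)
    return K


@dataclass
class DualSolution:
    """Solution of the dual QP in both (alpha, alpha*) and net-beta form."""

    alpha: np.ndarray
    alpha_star: np.ndarray
    objective: float
    n_iter: int
    converged: bool
    kkt_violation: float

    @property
    def beta(self) -> np.ndarray:
        """Net dual coefficients alpha - alpha*."""
        return self.alpha - self.alpha_star


def dual_objective(beta: np.ndarray, gram: np.ndarray, targets: np.ndarray, epsilon: float) -> float:
    """Dual objective evaluated at net coefficients (alpha + alpha* = |beta|)."""
    beta = np.asarray(beta, dtype=float)
    return float(0.5 * beta @ gram @ beta + epsilon * np.abs(beta).sum() - targets @ beta)


def _bias_intervals(beta: np.ndarray, e: np.ndarray, epsilon: float, C: float):
    """Per-point admissible interval [L_i, U_i] for the bias b.

    e_i = y_i - (K beta)_i.  KKT at optimum requires some common b in every
    interval; max(L) - min(U) is the violation the solver drives below
    tolerance.
    """
    thr = SV_THRESHOLD * max(C, 1.0)
    L = np.full(beta.shape, -np.inf)
    U = np.full(beta.shape, np.inf)
    at_up = beta >= C - thr
    at_lo = beta <= -C + thr
    pos = (beta > thr) & ~at_up
    neg = (beta < -thr) & ~at_lo
    zero = np.abs(beta) <= thr
    L[zero], U[zero] = e[zero] - epsilon, e[zero] + epsilon
    L[pos] = U[pos] = e[pos] - epsilon
    L[neg] = U[neg] = e[neg] + epsilon
    U[at_up] = e[at_up] - epsilon
    L[at_lo] = e[at_lo] + epsilon
    return L, U


def _pair_step(beta_i: float, beta_j: float, eta: float, grad: float, epsilon: float, C: float):
    """Exact minimizer of the two-variable subproblem.

    Minimize over delta (beta_i + delta, beta_j - delta kept feasible):
        D(delta) = 1/2 eta delta^2 + grad * delta
                   + eps (|beta_i + delta| - |beta_i| + |beta_j - delta| - |beta_j|)
    where eta = K_ii + K_jj - 2 K_ij >= 0 and grad = e_j - e_i.
    Piecewise quadratic with breakpoints at delta = -beta_i and delta = beta_j.
    """
    lo = max(-C - beta_i, beta_j - C)
    hi = min(C - beta_i, beta_j + C)
    if hi <= lo:
        return 0.0, 0.0

    def val(d: float) -> float:
        return (
            0.5 * eta * d * d
            + grad * d
            + epsilon * (abs(beta_i + d) - abs(beta_i) + abs(beta_j - d) - abs(beta_j))
        )

    candidates = {lo, hi}
    for bp in (-beta_i, beta_j):
        if lo < bp < hi:
            candidates.add(bp)
    if eta > 0:
        # stationary point of each smooth segment; val() is exact so spurious
        # out-of-segment candidates are harmless
        for s1 in (-1.0, 1.0):
            for s2 in (-1.0, 1.0):
                d = -(grad + epsilon * (s1 - s2)) / eta
                if lo <= d <= hi:
                    candidates.add(d)
    best_d, best_v = 0.0, 0.0
    for d in candidates:
        v = val(d)
        if v < best_v:
            best_d, best_v = d, v
    return best_d, best_v


def solve_dual(targets: np.ndarray, gram: np.ndarray, config: SVRConfig) -> DualSolution:
    """Solve the dual QP by maximal-violating-pair SMO updates.

    Starts from beta = 0 (feasible), repeatedly selects the pair (i, j) with
    the largest KKT inconsistency L_i - U_j and solves that two-variable
    subproblem exactly.  Deterministic for fixed inputs.
    """
    y = np.asarray(targets, dtype=float)
    K = np.asarray(gram, dtype=float)
    n = y.shape[0]
    if K.shape != (n, n):
        raise ValueError(f"gram must be {n}x{n}, got {K.shape}")
    C, eps, tol = config.C, config.epsilon, config.kkt_tolerance

    beta = np.zeros(n)
    e = y.copy()  # e_i = y_i - (K beta)_i, maintained incrementally
    it = 0
    violation = np.inf
    converged = False
    diagK = np.diag(K).copy()
    while it < config.max_passes:
        L, U = _bias_intervals(beta, e, eps, C)
        i = int(np.argmax(L))
        violation = float(L[i] - np.min(U))
        if violation < tol:
            converged = True
            break
        # second-order working-set selection: among points whose bias interval
        # is inconsistent with i's, pick the one with the largest estimated
        # objective gain (violation^2 / curvature); cures zigzag on
        # ill-conditioned Gram matrices
        viol_j = L[i] - U
        cand = viol_j > 0.0
        cand[i] = False
        eta_j = np.maximum(diagK[i] + diagK - 2.0 * K[i], 1e-12)
        gain = np.where(cand, viol_j**2 / eta_j, -np.inf)
        j = int(np.argmax(gain))
        eta = float(K[i, i] + K[j, j] - 2.0 * K[i, j])
        grad = float(e[j] - e[i])
        d, improvement = _pair_step(beta[i], beta[j], eta, grad, eps, C)
        if d == 0.0 or improvement >= 0.0:
            # numerically stalled below representable progress
            break
        beta[i] += d
        beta[j] -= d
        e -= (K[:, i] - K[:, j]) * d
        it += 1
        if it % 1024 == 0:
            e = y - K @ beta  # refresh against incremental-update drift
    if not converged:
        warnings.warn(
            f"SMO did not reach tolerance {tol:g} after {it} iterations "
            f"(worst KKT violation {violation:g})",
            RuntimeWarning,
        )
    np.clip(beta, -C, C, out=beta)
    alpha = np.maximum(beta, 0.0)
    alpha_star = np.maximum(-beta, 0.0)
    obj = dual_objective(beta, K, y, eps)
    return DualSolution(
        alpha=alpha,
        alpha_star=alpha_star,
        objective=obj,
        n_iter=it,
        converged=converged,
        kkt_violation=violation,
    )


def compute_bias(
    solution: DualSolution,
    gram: np.ndarray,
    targets: np.ndarray,
    epsilon: float,
    C: float,
) -> float:
    """Bias b averaged over the boundary conditions of standard support vectors.

    A standard support vector has a dual coefficient strictly inside (0, C);
    on the alpha side its condition is b = y_i - (K beta)_i - eps, on the
    alpha* side b = y_i - (K beta)_i + eps.  If no standard support vector
    exists the midpoint of the KKT-feasible bias interval is used.
    """
    beta = solution.beta
    y = np.asarray(targets, dtype=float)
    e = y - np.asarray(gram, dtype=float) @ beta
    thr = SV_THRESHOLD * max(C, 1.0)
    free_a = (solution.alpha > thr) & (solution.alpha < C - thr)
    free_as = (solution.alpha_star > thr) & (solution.alpha_star < C - thr)
    n_nsv = int(free_a.sum() + free_as.sum())
    if n_nsv > 0:
        total = float(np.sum(e[free_a] - epsilon) + np.sum(e[free_as] + epsilon))
        return total / n_nsv
    warnings.warn(
        "no standard support vectors; using midpoint of the KKT-feasible bias interval",
        RuntimeWarning,
    )
    L, U = _bias_intervals(beta, e, epsilon, C)
    lo, hi = float(np.max(L)), float(np.min(U))
    if not np.isfinite(lo):
        lo = hi
    if not np.isfinite(hi):
        hi = lo
    return 0.5 * (lo + hi)


@dataclass
class SurrogateModel:
    """Trained epsilon-SVR surrogate: support vectors, net coefficients, bias.

    ``scaling`` (a :class:`welanopt.data_prep.ScalingParams`) is attached so a
    downstream optimizer can move between raw condition units and the
    normalized scale the model was trained on.
    """

    support_vectors: np.ndarray
    coefficients: np.ndarray  # beta_i = alpha_i - alpha_i* over support vectors
    bias: float
    sigma: float
    config: SVRConfig
    scaling: object | None = None
    n_support: int = 0
    n_standard_support: int = 0
    dual_objective: float = 0.0
    converged: bool = True

    def predict(self, X: np.ndarray) -> np.ndarray | float:
        """Predicted normalized production for condition vector(s) ``X``."""
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        Xm = np.atleast_2d(X)
        if self.support_vectors.size == 0:
            out = np.full(Xm.shape[0], self.bias)
            return float(out[0]) if single else out
        if Xm.shape[1] != self.support_vectors.shape[1]:
            raise ValueError(
                f"dimension mismatch: model expects {self.support_vectors.shape[1]} "
                f"features, got {Xm.shape[1]}"
            )
        K = gram_matrix(Xm, self.sigma, other=self.support_vectors)
        out = K @ self.coefficients + self.bias
        return float(out[0]) if single else out

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "support_vectors": self.support_vectors.tolist(),
            "coefficients": self.coefficients.tolist(),
            "bias": self.bias,
            "sigma": self.sigma,
            "config": {
                "C": self.config.C,
                "epsilon": self.config.epsilon,
                "sigma": self.config.sigma,
                "kkt_tolerance": self.config.kkt_tolerance,
                "max_passes": self.config.max_passes,
            },
            "scaling": None if self.scaling is None else json.loads(self.scaling.to_json()),
            "n_support": self.n_support,
            "n_standard_support": self.n_standard_support,
            "dual_objective": self.dual_objective,
            "converged": self.converged,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SurrogateModel":
        from .data_prep import ScalingParams

        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        scaling = None
        if d.get("scaling") is not None:
            s = d["scaling"]
            scaling = ScalingParams(
                x_min=s["x_min"], x_max=s["x_max"], y_min=s["y_min"], y_max=s["y_max"]
            )
        return cls(
            support_vectors=np.asarray(d["support_vectors"], dtype=float),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            bias=float(d["bias"]),
            sigma=float(d["sigma"]),
            config=SVRConfig(**d["config"]),
            scaling=scaling,
            n_support=int(d["n_support"]),
            n_standard_support=int(d["n_standard_support"]),
            dual_objective=float(d["dual_objective"]),
            converged=bool(d["converged"]),
        )


def fit(
    X: np.ndarray,
    y: np.ndarray,
    config: SVRConfig,
    scaling: object | None = None,
) -> SurrogateModel:
    """Train the epsilon-SVR: Gram matrix -> dual solve -> bias -> model."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if len(X) != len(y):
        raise ValueError(f"{len(X)} inputs vs {len(y)} targets")
    if len(X) < 2:
        raise ValueError("need at least 2 training records")
    K = gram_matrix(X, config.sigma)
    sol = solve_dual(y, K, config)
    b = compute_bias(sol, K, y, config.epsilon, config.C)
    beta = sol.beta
    thr = SV_THRESHOLD * max(config.C, 1.0)
    sv_mask = np.abs(beta) > thr
    free = (np.abs(beta) > thr) & (np.abs(beta) < config.C - thr)
    return SurrogateModel(
        support_vectors=X[sv_mask],
        coefficients=beta[sv_mask],
        bias=b,
        sigma=config.sigma,
        config=config,
        scaling=scaling,
        n_support=int(sv_mask.sum()),
        n_standard_support=int(free.sum()),
        dual_objective=sol.objective,
        converged=sol.converged,
    )
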