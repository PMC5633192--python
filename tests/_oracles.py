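"""Independent reference solvers used only by the tests.

These deliberately avoid the package's own SMO code path: the enumeration
oracle walks every KKT active-set pattern of the dual QP (exact for small n),
the brute-force oracle scans a fine grid over the single free coefficient of
a two-point problem, and scikit-learn's SVR provides a third, externally
implemented fit of the same dual.
"""

import itertools

import numpy as np


def dual_objective_beta(beta, K, y, eps):
    beta = np.asarray(beta, dtype=float)
    return float(0.5 * beta @ K @ beta + eps * np.abs(beta).sum() - y @ beta)


def enumeration_qp_oracle(y, K, C, eps, tol=1e-9):
    """Exact dual optimum by enumerating KKT active sets in net-beta space.

    Each training point is assigned one of five statuses (beta at -C, free
    negative, zero, free positive, at C); for every assignment the stationary
    equations plus the sum constraint form a linear system, and any solution
    satisfying all KKT conditions is the global optimum of the convex QP.
    Cost 5^n — small n only.
    """
    y = np.asarray(y, dtype=float)
    K = np.asarray(K, dtype=float)
    n = len(y)
    best = np.inf
    for status in itertools.product((-2, -1, 0, 1, 2), repeat=n):
        st = np.array(status)
        beta = np.where(st == -2, -C, np.where(st == 2, C, 0.0)).astype(float)
        free = (st == -1) | (st == 1)
        sign = np.sign(st).astype(float)
        F = np.flatnonzero(free)
        m = len(F)
        if m:
            M = np.zeros((m + 1, m + 1))
            M[:m, :m] = K[np.ix_(F, F)]
            M[:m, m] = 1.0
            M[m, :m] = 1.0
            rhs = np.concatenate(
                [y[F] - eps * sign[F] - K[np.ix_(F, ~free)] @ beta[~free],
                 [-beta[~free].sum()]]
            )
            sol, *_ = np.linalg.lstsq(M, rhs, rcond=None)
            if not np.allclose(M @ sol, rhs, atol=1e-8):
                continue
            bF, lam = sol[:m], sol[m]
            beta[F] = bF
            if np.any(sign[F] * bF < tol) or np.any(np.abs(bF) > C - tol):
                continue
        else:
            if abs(beta.sum()) > 1e-12:
                continue
            lam = None
        g_all = K @ beta - y
        if lam is None:
            lo, hi = -np.inf, np.inf
            for i in range(n):
                if st[i] == 0:
                    lo, hi = max(lo, -g_all[i] - eps), min(hi, -g_all[i] + eps)
                elif st[i] == 2:
                    hi = min(hi, -g_all[i] - eps)
                else:
                    lo = max(lo, -g_all[i] + eps)
            if lo > hi + tol:
                continue
        else:
            ok = True
            for i in range(n):
                gi = g_all[i] + lam
                if st[i] == 0 and abs(gi) > eps + tol:
                    ok = False
                    break
                if st[i] == 2 and gi + eps > tol:
                    ok = False
                    break
                if st[i] == -2 and gi - eps < -tol:
                    ok = False
                    break
            if not ok:
                continue
        best = min(best, dual_objective_beta(beta, K, y, eps))
    return best


def two_point_brute_force(y, K, C, eps, grid_size=2_000_001):
    """Dual optimum of a 2-point problem by scanning the free coefficient.

    The equality constraint forces beta_2 = -beta_1, leaving one scalar in
    [-C, C]; the minimum over a fine grid bounds the optimum from above.
    """
    assert len(y) == 2
    b = np.linspace(-C, C, grid_size)
    eta = K[0, 0] + K[1, 1] - 2 * K[0, 1]
    obj = 0.5 * eta * b**2 + 2 * eps * np.abs(b) - (y[0] - y[1]) * b
    return float(obj.min())
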