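"""Independent oracles used across the test modules.

Every function here re-derives a quantity by a route deliberately different
from the package implementation (brute force, enumeration, closed form, or a
third-party solver), so agreement is evidence and not tautology.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from scipy.optimize import nnls


def pearson_sigma_formula(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook sum-formula Pearson correlation (no numpy.corrcoef)."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx, syy, sxy = sum(v * v for v in x), sum(v * v for v in y), sum(
        a * b for a, b in zip(x, y)
    )
    num = n * sxy - sx * sy
    den = np.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    return num / den


def n2en_objective(X, y, a, g1, g2) -> float:
    r = y - X @ a
    return float(r @ r + g1 * np.sum(np.abs(a)) + g2 * a @ a)


def n2en_bruteforce(X: np.ndarray, y: np.ndarray, g1: float, g2: float):
    """Global optimum of the non-negative elastic net by exhaustive
    enumeration of support sets (feasible only for small feature counts).

    On each candidate support the stationarity system
    (X_S' X_S + g2 I) a_S = X_S' y - g1/2 is solved; solutions with any
    negative entry are infeasible as interior points of that support and are
    discarded (the true optimum appears as the interior solution of its own
    support).  Returns (a_opt, objective).
    """
    n, M = X.shape
    best_a = np.zeros(M)
    best_obj = n2en_objective(X, y, best_a, g1, g2)
    for size in range(1, M + 1):
        for S in itertools.combinations(range(M), size):
            S = list(S)
            XS = X[:, S]
            A = XS.T @ XS + g2 * np.eye(size)
            rhs = XS.T @ y - g1 / 2.0
            try:
                aS = np.linalg.solve(A, rhs)
            except np.linalg.LinAlgError:
                continue
            if np.any(aS < 0):
                continue
            a = np.zeros(M)
            a[S] = aS
            obj = n2en_objective(X, y, a, g1, g2)
            if obj < best_obj - 1e-15:
                best_a, best_obj = a, obj
    return best_a, best_obj


def n2en_nnls_oracle(X: np.ndarray, y: np.ndarray, g1: float, g2: float) -> np.ndarray:
    """Exact global solution via completing the square and Lawson-Hanson NNLS.

    ||y-Xa||^2 + g1 1'a + g2||a||^2 = ||B a - c||^2 + const with
    B'B = X'X + g2 I and B'c = X'y - g1/2.  Requires g2 > 0 or full-rank X.
    """
    M = X.shape[1]
    H = X.T @ X + g2 * np.eye(M)
    B = cholesky(H, lower=False)
    c = solve_triangular(B.T, X.T @ y - g1 / 2.0, lower=True)
    a, _ = nnls(B, c)
    return a


def fisher_direction(Z: np.ndarray, y01: np.ndarray) -> np.ndarray:
    """Classical Fisher linear discriminant w = S_w^{-1} (mu1 - mu0)."""
    Z0, Z1 = Z[y01 == 0], Z[y01 == 1]
    mu0, mu1 = Z0.mean(0), Z1.mean(0)
    Sw = (Z0 - mu0).T @ (Z0 - mu0) + (Z1 - mu1).T @ (Z1 - mu1)
    return np.linalg.solve(Sw, mu1 - mu0)


def clustering_bruteforce(W: np.ndarray) -> np.ndarray:
    """Weighted clustering coefficient by explicit triangle enumeration."""
    W = np.abs(W)
    m = W.shape[0]
    wmax = W.max()
    out = np.zeros(m)
    if wmax == 0:
        return out
    Wn = W / wmax
    for i in range(m):
        k = int((W[i] > 0).sum())
        if k < 2:
            continue
        s = 0.0
        for j in range(m):
            for h in range(m):
                if j != i and h != i and j != h:
                    s += (Wn[i, j] * Wn[i, h] * Wn[j, h]) ** (1.0 / 3.0)
        out[i] = s / (k * (k - 1))
    return out


def equicorrelation_eigenvalues(m: int, rho: float) -> np.ndarray:
    """Analytic spectrum of (1-rho) I + rho J: 1+(m-1)rho once, 1-rho (m-1)x."""
    return np.array([1 + (m - 1) * rho] + [1 - rho] * (m - 1))
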