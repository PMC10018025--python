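"""Independent brute-force oracles used to check the package's numerics.

Everything here is implemented from first principles (direct formula
evaluation, exact combinatorics, dense eigen-decompositions) and never
calls into :mod:`cortexlink`.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import scipy.linalg


def bh_oracle(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted values by the textbook step-up definition:
    q_(i) = min_{k >= i} p_(k) * m / k over the sorted p-values."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = running
    return q


def hypergeom_tail_oracle(k: int, M: int, K: int, n: int) -> Fraction:
    """Exact rational P(X >= k) for X ~ Hypergeometric(M, K, n)."""
    total = comb(M, n)
    upper = min(K, n)
    acc = sum(comb(K, x) * comb(M - K, n - x)
              for x in range(k, upper + 1) if n - x <= M - K)
    return Fraction(acc, total)


def pooled_t_oracle(a, b) -> float:
    """Two-sample pooled-variance t statistic by the textbook formula."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))


def paired_t_oracle(d) -> float:
    d = np.asarray(d, dtype=float)
    return d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))


def ols_residual_oracle(X, y) -> np.ndarray:
    """Residuals from solving the normal equations directly."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return y - X @ beta


def pls1_weights_oracle(X, y) -> np.ndarray:
    """Closed-form first-component weights for a univariate response:
    z-score columns of X, center y, normalize X_cᵀ y_c to unit length."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Xc = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    yc = y - y.mean()
    w = Xc.T @ yc
    return w / np.linalg.norm(w)


def cca_corr_oracle(X, Y, standardize: bool = True) -> np.ndarray:
    """Canonical correlations from the generalized eigenproblem
    Sxy Syy⁻¹ Syx a = rho² Sxx a, solved densely."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    if standardize:
        Xc = Xc / X.std(axis=0, ddof=1)
        Yc = Yc / Y.std(axis=0, ddof=1)
    n = len(X)
    Sxx = Xc.T @ Xc / (n - 1)
    Syy = Yc.T @ Yc / (n - 1)
    Sxy = Xc.T @ Yc / (n - 1)
    A = Sxy @ np.linalg.solve(Syy, Sxy.T)
    vals = scipy.linalg.eigh(A, Sxx, eigvals_only=True)
    vals = np.clip(vals, 0.0, 1.0)
    rho = np.sqrt(np.sort(vals)[::-1])
    return rho[: min(X.shape[1], Y.shape[1])]


def laplacian_score_oracle(X, k: int):
    """Laplacian scores by explicit loops: k-NN heat graph over rows of X,
    then the ratio x̃ᵀ L x̃ / x̃ᵀ D x̃ evaluated with dense matrix products."""
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    d2 = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d2[i, j] = float(((X[i] - X[j]) ** 2).sum())
    neighbours = []
    sq_sum, sq_count = 0.0, 0
    for i in range(n):
        order = sorted(range(n), key=lambda j: (d2[i, j], j))
        nn = [j for j in order if j != i][:k]
        neighbours.append(set(nn))
        for j in nn:
            sq_sum += d2[i, j]
            sq_count += 1
    sigma = sq_sum / sq_count if sq_sum > 0 else 1.0
    S = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j and (j in neighbours[i] or i in neighbours[j]):
                S[i, j] = np.exp(-d2[i, j] / sigma)
    D = np.diag(S.sum(axis=1))
    L = D - S
    ones = np.ones(n)
    scores = np.full(m, np.nan)
    for r in range(m):
        x = X[:, r]
        if np.ptp(x) == 0:
            continue
        xt = x - (x @ D @ ones) / (ones @ D @ ones) * ones
        scores[r] = (xt @ L @ xt) / (xt @ D @ xt)
    return scores
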