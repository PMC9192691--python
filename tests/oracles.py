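"""Independent reference implementations used only as test oracles.

These deliberately avoid the code paths of the package under test:
the LASSO oracle is a plain cyclic coordinate-descent loop in numpy
(no scikit-learn), the hypergeometric oracle enumerates combinations
exactly, and the MCL oracle is a line-by-line transcription of the
expansion/inflation recursion.
"""

from __future__ import annotations

from math import comb

import numpy as np


def cd_lasso(X: np.ndarray, y: np.ndarray, lam: float, n_sweeps: int = 2000,
             tol: float = 1e-12) -> np.ndarray:
    """Cyclic coordinate descent for (1/2n)||y - Xb||^2 + lam*||b||_1."""
    n, m = X.shape
    beta = np.zeros(m)
    col_sq = (X**2).sum(axis=0) / n
    resid = y.copy()
    for _ in range(n_sweeps):
        max_delta = 0.0
        for j in range(m):
            if col_sq[j] == 0:
                continue
            rho = X[:, j] @ resid / n + col_sq[j] * beta[j]
            new = np.sign(rho) * max(abs(rho) - lam, 0.0) / col_sq[j]
            delta = new - beta[j]
            if delta != 0.0:
                resid -= delta * X[:, j]
                beta[j] = new
                max_delta = max(max_delta, abs(delta))
        if max_delta < tol:
            break
    return beta


def entry_lambdas_dense(X: np.ndarray, y: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Per-feature entry lambda by solving independently at every grid point."""
    m = X.shape[1]
    entry = np.full(m, np.nan)
    for lam in sorted(grid, reverse=True):
        beta = cd_lasso(X, y, lam)
        newly = (beta != 0) & np.isnan(entry)
        entry[newly] = lam
    return entry


def exact_hypergeom_upper(overlap: int, query_n: int, set_n: int,
                          background_n: int) -> float:
    """P(X >= overlap) by direct summation of exact binomial-coefficient terms."""
    total = comb(background_n, query_n)
    acc = 0
    for k in range(overlap, min(query_n, set_n) + 1):
        acc += comb(set_n, k) * comb(background_n - set_n, query_n - k)
    return acc / total


def mcl_reference(adj: np.ndarray, inflation: float = 2.0, max_iter: int = 200,
                  tol: float = 1e-10) -> list[set[int]]:
    """Straightforward MCL on a dense adjacency matrix; returns node clusters."""
    m = adj.astype(float).copy()
    np.fill_diagonal(m, 1.0)
    m = m / m.sum(axis=0)
    for _ in range(max_iter):
        new = m @ m
        new = new**inflation
        new = new / new.sum(axis=0)
        if np.abs(new - m).max() < tol:
            m = new
            break
        m = new
    clusters = []
    for i in range(m.shape[0]):
        if m[i, i] > 1e-6:
            members = {j for j in range(m.shape[1]) if m[i, j] > 1e-6}
            for c in clusters:
                if c & members:
                    c |= members
                    break
            else:
                clusters.append(members)
    return clusters
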