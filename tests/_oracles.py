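"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid scipy and the package's own code paths: ranks are
assigned by explicit sorting with hand-averaged ties, Spearman rho comes
from the explicit product-moment formula on ranks, and OLS residuals come
from the normal equations solved directly.
"""

import numpy as np


def oracle_ranks(x):
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0  # mean of 1-based positions i..j
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def oracle_pearson(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float(np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2)))


def oracle_spearman(x, y):
    return oracle_pearson(oracle_ranks(x), oracle_ranks(y))


def oracle_spearman_d2(x, y):
    """Classical 1 - 6*sum(d^2)/(n(n^2-1)) formula; exact only without ties."""
    rx = oracle_ranks(x)
    ry = oracle_ranks(y)
    n = len(rx)
    d2 = np.sum((rx - ry) ** 2)
    return float(1.0 - 6.0 * d2 / (n * (n**2 - 1)))


def oracle_ols_residuals(y, Z):
    """Residuals of y on [1, Z] via the normal equations."""
    y = np.asarray(y, dtype=float)
    Z = np.asarray(Z, dtype=float)
    X = np.column_stack([np.ones(len(y)), Z])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return y - X @ beta


def oracle_partial_spearman(x, y, Z):
    rx = oracle_ols_residuals(x, Z)
    ry = oracle_ols_residuals(y, Z)
    return oracle_spearman(rx, ry)
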