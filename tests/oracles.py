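"""Independent brute-force oracles used by the test suite.

These implementations deliberately avoid the library's code paths: plain
Python loops over the printed formulas, scipy's Gaussian pdf for kernels and
exhaustive enumeration for the rank test, so that agreement with the package
is a genuine cross-check.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy.stats import norm


def moments_bruteforce(a) -> tuple[float, float, float, float]:
    """Mean, sample std, standardized skewness and raw kurtosis by loops."""
    a = list(map(float, a))
    n = len(a)
    mu = sum(a) / n
    sigma = math.sqrt(sum((x - mu) ** 2 for x in a) / (n - 1))
    s = sum(((x - mu) / sigma) ** 3 for x in a) / n
    k = sum(((x - mu) / sigma) ** 4 for x in a) / n
    return mu, sigma, s, k


def kde_bruteforce(a, grid, bandwidth: float) -> np.ndarray:
    """Sum of scipy Gaussian pdfs, one grid point at a time."""
    out = []
    for x in grid:
        out.append(sum(norm.pdf(x, loc=v, scale=bandwidth) for v in a) / len(a))
    return np.asarray(out)


def pdf_cov_bruteforce(pdfs) -> np.ndarray:
    """Sample covariance matrix between PDFs by an explicit double loop."""
    F = np.asarray(pdfs, float)
    W, L = F.shape
    means = F.mean(axis=1)
    C = np.zeros((W, W))
    for i in range(W):
        for j in range(W):
            C[i, j] = sum(
                (F[i, x] - means[i]) * (F[j, x] - means[j]) for x in range(L)
            ) / (L - 1)
    return C


def nft_filter_permuted_order(ft, ft_max=3.0, interval=(-1.27, 1.7)) -> np.ndarray:
    """Deliberately wrong step order: detrend -> threshold -> interval."""
    v = np.asarray(ft, float)
    v = v - v.mean()
    v = v[v <= ft_max]
    return v[(v >= interval[0]) & (v <= interval[1])]


def mannwhitney_exact_p(x, y) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney p by enumerating group assignments.

    Assumes no ties. Returns (U of x, p). U counts pairs where an x value
    exceeds a y value.
    """
    x, y = list(x), list(y)
    pooled = x + y
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    n1 = len(x)

    def u_of(group):
        rest = [v for v in pooled if v not in group]
        return sum(1 for a in group for b in rest if a > b)

    u_obs = sum(1 for a in x for b in y if a > b)
    us = [u_of(list(c)) for c in combinations(pooled, n1)]
    us = np.asarray(us, float)
    p = 2.0 * min(np.mean(us <= u_obs), np.mean(us >= u_obs))
    return float(u_obs), float(min(1.0, p))
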