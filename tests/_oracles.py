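"""Independent reference implementations used to validate the package.

These deliberately re-derive each statistic from its definition with the
simplest possible code (explicit loops, no shared code with the package),
so that agreement is evidence of correctness rather than of shared bugs.
"""

from __future__ import annotations

import numpy as np


def ssgsea_brute(values: dict[str, float], gene_set: set[str], tau: float) -> float:
    """Weighted-ECDF ssGSEA statistic by direct enumeration.

    Walk the genes in descending expression order (ties by name); at each
    position accumulate the weighted in-set ECDF (weights = rank value^tau,
    rank value n..1 from the top) minus the unweighted out-of-set ECDF, and
    sum the differences.
    """
    items = sorted(values.items(), key=lambda kv: (-kv[1], kv[0]))
    n = len(items)
    in_set = [g.upper() in {x.upper() for x in gene_set} for g, _ in items]
    m = sum(in_set)
    assert 0 < m < n
    total_w = sum((n - i) ** tau for i in range(n) if in_set[i])
    score = 0.0
    cum_in = 0.0
    cum_out = 0
    for i in range(n):
        if in_set[i]:
            cum_in += (n - i) ** tau
        else:
            cum_out += 1
        score += cum_in / total_w - cum_out / (n - m)
    return score


def nnls_projected_gradient(
    K: np.ndarray, t: np.ndarray, tol: float = 1e-13, max_iter: int = 200_000
) -> np.ndarray:
    """Non-negative least squares by accelerated projected gradient descent.

    Minimizes ||K x - t||^2 subject to x >= 0 with FISTA-style momentum;
    terminates on a KKT-style fixed-point criterion.
    """
    K = np.asarray(K, dtype=float)
    t = np.asarray(t, dtype=float)
    L = np.linalg.norm(K, 2) ** 2
    x = np.zeros(K.shape[1])
    y = x.copy()
    momentum = 1.0
    for _ in range(max_iter):
        grad = K.T @ (K @ y - t)
        x_new = np.maximum(0.0, y - grad / L)
        momentum_new = (1.0 + np.sqrt(1.0 + 4.0 * momentum**2)) / 2.0
        y = x_new + (momentum - 1.0) / momentum_new * (x_new - x)
        if np.max(np.abs(x_new - x)) < tol:
            x = x_new
            break
        x, momentum = x_new, momentum_new
    return x


def welch_t(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook Welch (unequal variance) two-sample t-statistic."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    vx = x.var(ddof=1) / len(x)
    vy = y.var(ddof=1) / len(y)
    return float((x.mean() - y.mean()) / np.sqrt(vx + vy))


def beta_method_of_moments(samples: np.ndarray) -> tuple[float, float]:
    """Method-of-moments estimates of beta shape parameters."""
    m = samples.mean()
    v = samples.var()
    common = m * (1.0 - m) / v - 1.0
    return m * common, (1.0 - m) * common


def origin_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Closed-form intercept-free regression slope of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.sum(x * y) / np.sum(x * x))
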