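"""Independent brute-force oracles used only by the tests.

Each function re-derives a quantity by the most transparent method available
(exhaustive enumeration, two-pass arithmetic, explicit order statistics) and
never calls the implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def pinball(u, tau):
    u = np.asarray(u, dtype=float)
    return float(np.sum(np.where(u >= 0, tau * u, (tau - 1.0) * u)))


def vertex_enumeration_qr(X, y, tau):
    """Exact quantile-regression minimum by enumerating basic solutions.

    An optimal solution passes through p data points (a vertex of the LP),
    so trying every nonsingular p-subset and scoring the pinball loss finds
    the global minimum for small n.
    Returns (best_loss, best_beta).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    best = (np.inf, None)
    for rows in itertools.combinations(range(n), p):
        A = X[list(rows)]
        if abs(np.linalg.det(A)) < 1e-12:
            continue
        beta = np.linalg.solve(A, y[list(rows)])
        loss = pinball(y - X @ beta, tau)
        if loss < best[0] - 1e-15:
            best = (loss, beta)
    return best


def two_pass_moments(x):
    """Textbook two-pass mean and (n-1)-denominator SD."""
    x = np.asarray(x, dtype=float)
    n = x.size
    mean = float(sum(x) / n)
    ss = float(sum((v - mean) ** 2 for v in x))
    sd = (ss / (n - 1)) ** 0.5 if n > 1 else None
    return mean, sd


def count_transitions(colors_a, colors_b):
    """3x3 pair counts by explicit looping."""
    counts = {}
    for a, b in zip(colors_a, colors_b):
        counts[(a, b)] = counts.get((a, b), 0) + 1
    return counts


def order_statistic_quantile(x, q):
    """Linear interpolation between order statistics at position (n-1)q."""
    xs = sorted(float(v) for v in x)
    h = (len(xs) - 1) * q
    lo = int(np.floor(h))
    hi = min(lo + 1, len(xs) - 1)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])
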