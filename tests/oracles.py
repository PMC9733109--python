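"""Independent brute-force oracles for the exact tests.

These enumerate the full null distribution directly and never call the
implementations they are used to check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def binom_pmf(n: int, p0: float) -> list[float]:
    return [math.comb(n, i) * p0**i * (1 - p0) ** (n - i) for i in range(n + 1)]


def binom_two_sided(k: int, n: int, p0: float) -> float:
    """Minlike convention: sum of outcome probabilities <= P(observed)."""
    pmf = binom_pmf(n, p0)
    obs = pmf[k]
    return min(1.0, sum(p for p in pmf if p <= obs * (1 + 1e-12)))


def binom_greater(k: int, n: int, p0: float) -> float:
    return min(1.0, sum(binom_pmf(n, p0)[k:]))


def binom_less(k: int, n: int, p0: float) -> float:
    return min(1.0, sum(binom_pmf(n, p0)[: k + 1]))


def mann_whitney_two_sided(x, y) -> float:
    """Exact two-sided p by enumerating all rank assignments (no ties)."""
    x, y = list(map(float, x)), list(map(float, y))
    n, m = len(x), len(y)
    u_obs = sum(xi > yj for xi in x for yj in y)
    pooled_ranks = range(1, n + m + 1)
    us = []
    for combo in itertools.combinations(pooled_ranks, n):
        us.append(sum(combo) - n * (n + 1) / 2)
    us = np.array(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return min(1.0, 2 * min(p_le, p_ge))


def signed_rank_two_sided(d) -> float:
    """Exact two-sided p by enumerating all sign assignments (no ties/zeros)."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    order = np.argsort(np.abs(d))
    ranks = np.empty(len(d))
    ranks[order] = np.arange(1, len(d) + 1)
    v_obs = ranks[d > 0].sum()
    vs = []
    for signs in itertools.product([0, 1], repeat=len(d)):
        vs.append(sum(r for r, s in zip(ranks, signs) if s))
    vs = np.array(vs)
    p_le = np.mean(vs <= v_obs)
    p_ge = np.mean(vs >= v_obs)
    return min(1.0, 2 * min(p_le, p_ge))


def friedman_statistic(y: np.ndarray) -> float:
    """Direct rank-sum arithmetic (no ties expected)."""
    y = np.asarray(y, dtype=float)
    n, k = y.shape
    ranks = np.argsort(np.argsort(y, axis=1), axis=1) + 1.0
    rj = ranks.sum(axis=0)
    return 12.0 / (n * k * (k + 1)) * float((rj**2).sum()) - 3.0 * n * (k + 1)
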