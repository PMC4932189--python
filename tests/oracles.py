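"""Independent brute-force oracles used only by the test suite.

Everything here is written in the most literal way possible (explicit
loops, itertools enumeration) and shares no code with the package's
vectorized implementations, so agreement between the two is meaningful.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def naive_energy(x, y, alpha=1.0):
    """Energy divergence by explicit double loops; returns (e_hat, q_hat)."""
    x = list(map(float, x))
    y = list(map(float, y))
    n, m = len(x), len(y)
    between = 0.0
    for xi in x:
        for yj in y:
            between += abs(xi - yj) ** alpha
    within_x = 0.0
    for i in range(n):
        for k in range(i + 1, n):
            within_x += abs(x[i] - x[k]) ** alpha
    within_y = 0.0
    for j in range(m):
        for l in range(j + 1, m):
            within_y += abs(y[j] - y[l]) ** alpha
    e = (
        2.0 * between / (n * m)
        - within_x / (n * (n - 1) / 2)
        - within_y / (m * (m - 1) / 2)
    )
    q = n * m / (n + m) * e
    return e, q


def exhaustive_best_split(z, min_size, alpha=1.0):
    """Try every admissible split position; ties -> smallest position."""
    z = list(map(float, z))
    n = len(z)
    if n < 2 * min_size:
        return None
    best_k, best_q = None, -math.inf
    for k in range(min_size, n - min_size + 1):
        _, q = naive_energy(z[:k], z[k:], alpha)
        if q > best_q:
            best_k, best_q = k, q
    return best_k, best_q


def naive_mde_counts(intervals, t_max):
    """Per-slice event counts by per-event, per-slice double loop.

    ``intervals`` are already-rounded integer (young, old) pairs; events
    entirely older than ``t_max`` are dropped, others clipped.  Returns
    counts indexed by age 0..t_max ascending.
    """
    counts = [0] * (t_max + 1)
    for young, old in intervals:
        if young > t_max:
            continue
        for t in range(t_max + 1):
            if young <= t <= min(old, t_max):
                counts[t] += 1
    return counts


def exhaustive_permutation_pvalue(z, min_size, alpha=1.0):
    """Exact permutation p-value of the best split over ALL permutations.

    Only feasible for very short series (len <= 8).  The observed statistic
    is the best-split q of the identity ordering; the null enumerates every
    ordering of the observations.
    """
    z = list(map(float, z))
    _, observed = exhaustive_best_split(z, min_size, alpha)
    thresh = observed - 1e-9 * (1.0 + abs(observed))  # count exact ties
    total = 0
    exceed = 0
    for perm in itertools.permutations(z):
        total += 1
        _, q = exhaustive_best_split(list(perm), min_size, alpha)
        if q >= thresh:
            exceed += 1
    return exceed / total
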