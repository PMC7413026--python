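"""Independent brute-force oracles used to validate the package's statistics.

These deliberately re-derive each quantity from first principles
(definitions, enumeration) rather than calling the code paths they check.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import hypergeom


def bh_adjust_bruteforce(p):
    """Literal step-up definition: adj_(i) = min_{j>=i} p_(j) * m / j."""
    p = list(map(float, p))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [None] * m
    for rank_pos, i in enumerate(order):
        candidates = []
        for later_pos in range(rank_pos, m):
            j = later_pos + 1
            candidates.append(p[order[later_pos]] * m / j)
        adjusted[i] = min(1.0, min(candidates))
    return adjusted


def fisher_exact_bruteforce(table):
    """Two-sided Fisher p by enumerating all tables with the same margins
    and summing hypergeometric probabilities <= that of the observed table."""
    (a, b), (c, d) = table
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2
    p_obs = hypergeom.pmf(a, n, row1, col1)
    total = 0.0
    for x in range(max(0, col1 - row2), min(col1, row1) + 1):
        px = hypergeom.pmf(x, n, row1, col1)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(1.0, total)


def kendall_tau_b_bruteforce(x, y):
    """tau-b by O(n^2) concordant/discordant pair enumeration with tie terms."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    concordant = discordant = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                concordant += 1
            else:
                discordant += 1
    denom = math.sqrt((concordant + discordant + tx) * (concordant + discordant + ty))
    if denom == 0:
        return np.nan
    return (concordant - discordant) / denom


def roe_bruteforce(observed):
    """R_O/E from the chi-square independence expected counts."""
    obs = np.asarray(observed, dtype=float)
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    return obs / expected
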