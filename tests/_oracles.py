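"""Independent brute-force oracles used to validate the statistical core.

These deliberately avoid scipy/statsmodels: Fisher's exact test is computed
by exhaustive hypergeometric enumeration with exact integer arithmetic, and
Benjamini-Hochberg by a literal step-up transcription.
"""
from __future__ import annotations

from math import comb


def fisher_two_sided(m1: int, u1: int, m2: int, u2: int) -> float:
    """Two-sided Fisher's exact p for [[m1, u1], [m2, u2]] by enumerating
    every 2x2 table with the observed margins and summing the probabilities
    of all tables no more likely than the observed one (exact integer
    comparison of hypergeometric weights)."""
    r1, r2 = m1 + u1, m2 + u2
    c1 = m1 + m2
    denom = comb(r1 + r2, c1)
    w_obs = comb(r1, m1) * comb(r2, c1 - m1)
    total = 0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        w = comb(r1, k) * comb(r2, c1 - k)
        if w <= w_obs:
            total += w
    return total / denom


def bh_step_up(pvals) -> list[float]:
    """Benjamini-Hochberg q-values: q_(k) = min_{j >= k} (n/j) p_(j), cap 1."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    q_sorted = [0.0] * n
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * n / rank)
        q_sorted[rank - 1] = running
    out = [0.0] * n
    for rank, i in enumerate(order):
        out[i] = q_sorted[rank]
    return out
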