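"""Independent brute-force oracles used only by the tests.

These deliberately avoid the code paths they check: the Fisher oracle sums
hypergeometric pmf terms with exact integer binomials, and the BH oracle is
the textbook step-up procedure written directly.
"""

from math import comb

import numpy as np


def fisher_one_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment in row 1) Fisher p for [[a, b], [c, d]].

    Full enumeration of the hypergeometric distribution with fixed margins:
    row1 = a+b draws, a+c successes, population a+b+c+d.
    """
    row1, succ, n = a + b, a + c, a + b + c + d
    denom = comb(n, row1)
    lo, hi = max(0, row1 - (n - succ)), min(row1, succ)
    total = 0
    for k in range(a, hi + 1):
        total += comb(succ, k) * comb(n - succ, row1 - k)
    if a < lo:
        return 1.0
    return total / denom


def bh_step_up_oracle(p_values, fdr: float = 0.05):
    """Textbook Benjamini-Hochberg: q_(i) = min_{j>=i} p_(j)·n/j, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q, q <= fdr
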