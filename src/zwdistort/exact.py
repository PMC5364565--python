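"""Exact conditional tests on 2 x k contingency tables.

Implements the two-sided exact conditional test with both margins fixed: the
Fisher exact test for 2 x 2 tables and its Freeman-Halton extension for
2 x k tables (k >= 3 arises when genotyping error introduces a third genotype
code into an otherwise two-class pseudo-testcross marker).

The p-value follows the standard "sum of as-or-less-probable tables"
convention: all tables with the observed margins whose conditional
(multivariate hypergeometric) probability does not exceed that of the
observed table contribute.  All probabilities are computed in exact integer
arithmetic — the numerator of each table's probability over the common
denominator ``C(N, r1)`` — so tie inclusion is exact and the returned float
is correct to full double precision.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np

__all__ = ["exact_conditional_p"]


def _enumerate_numerators(cols: list[int], r1: int):
    """Yield the integer numerator Prod_j C(c_j, a_j) for every row-1 split.

    ``a_j`` is the row-1 count in column j; splits are enumerated under the
    margin constraint sum a_j = r1, 0 <= a_j <= c_j.
    """
    k = len(cols)
    suffix_max = np.cumsum([0] + cols[::-1])[::-1]  # max mass available from col j on

    def rec(j: int, remaining: int, num: int):
        if j == k - 1:
            if remaining <= cols[j]:
                yield num * comb(cols[j], remaining)
            return
        lo = max(0, remaining - int(suffix_max[j + 1]))
        hi = min(cols[j], remaining)
        for a in range(lo, hi + 1):
            yield from rec(j + 1, remaining - a, num * comb(cols[j], a))

    yield from rec(0, r1, 1)


def exact_conditional_p(table) -> float:
    """Two-sided exact conditional p-value for a 2 x k count table.

    Returns ``nan`` when either row is empty (the conditional distribution is
    degenerate and the test undefined), and 1.0 when at most one column is
    non-empty.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.shape[0] != 2:
        raise ValueError("expected a 2 x k table")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    r1, r2 = int(t[0].sum()), int(t[1].sum())
    if r1 == 0 or r2 == 0:
        return float("nan")
    keep = t.sum(axis=0) > 0
    t = t[:, keep]
    if t.shape[1] <= 1:
        return 1.0

    cols = [int(c) for c in t.sum(axis=0)]
    obs_num = 1
    for j in range(t.shape[1]):
        obs_num *= comb(cols[j], int(t[0, j]))
    total = comb(r1 + r2, r1)
    acc = 0
    for num in _enumerate_numerators(cols, r1):
        if num <= obs_num:
            acc += num
    return float(Fraction(acc, total))
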