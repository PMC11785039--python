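"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the code paths (and, where feasible, the libraries)
they check: the Fisher oracle enumerates every 2x2 table with the observed
margins and sums hypergeometric point masses computed from factorials; the BH
oracle applies the quadratic step-up definition directly; the ANOVA oracle is
the textbook balanced two-way sums-of-squares decomposition.
"""

import math

import numpy as np
from scipy import stats


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration over fixed margins."""
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def point_prob(x: int) -> float:
        # hypergeometric pmf via log-factorials
        return math.exp(
            math.lgamma(row1 + 1) - math.lgamma(x + 1) - math.lgamma(row1 - x + 1)
            + math.lgamma(row2 + 1) - math.lgamma(col1 - x + 1)
            - math.lgamma(row2 - col1 + x + 1)
            + math.lgamma(col1 + 1) + math.lgamma(n - col1 + 1) - math.lgamma(n + 1)
        )

    lo = max(0, col1 - row2)
    hi = min(row1, col1)
    p_obs = point_prob(a)
    total = 0.0
    for x in range(lo, hi + 1):
        px = point_prob(x)
        if px <= p_obs * (1 + 1e-7):
            total += px
    return min(total, 1.0)


def bh_stepup_naive(p_values) -> np.ndarray:
    """Quadratic-time Benjamini-Hochberg step-up q-values, input order.

    q_i = min over sorted positions j with p_(j) >= p_i of m * p_(j) / j,
    capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    ps = np.sort(p)
    ranks = np.arange(1, m + 1)
    q = np.empty(m)
    for i in range(m):
        mask = ps >= p[i]
        q[i] = min(1.0, float((m * ps[mask] / ranks[mask]).min()))
    return q


def balanced_two_way_anova_oracle(values: np.ndarray):
    """(F, p) for the interaction of a balanced 2x2xr layout.

    ``values`` has shape (2, 2, r): factor A x factor B x replicates.
    Textbook decomposition: SS_AB = r * sum (cell - row - col + grand)^2 on
    means, tested against SS_error with (N - 4) degrees of freedom.
    """
    a_levels, b_levels, r = values.shape
    assert a_levels == b_levels == 2
    grand = values.mean()
    cell = values.mean(axis=2)
    row = values.mean(axis=(1, 2))
    col = values.mean(axis=(0, 2))
    ss_int = r * ((cell - row[:, None] - col[None, :] + grand) ** 2).sum()
    ss_err = ((values - cell[:, :, None]) ** 2).sum()
    df_err = values.size - 4
    F = (ss_int / 1.0) / (ss_err / df_err)
    return F, float(stats.f.sf(F, 1, df_err))
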