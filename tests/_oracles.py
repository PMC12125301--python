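"""Independent brute-force oracles used only by the tests.

These deliberately re-derive quantities from first principles (O(N^2)
definitions, dynamic programming, direct enumeration) so they share no code
path with the implementations they check.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import hypergeom


def edit_distance_dp(a: str, b: str) -> int:
    """Textbook dynamic-programming Levenshtein distance."""
    m, n = len(a), len(b)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (a[i - 1] != b[j - 1]),
            )
        prev = cur
    return prev[n]


def gini_pairwise(sizes) -> float:
    """O(N^2) mean-absolute-difference definition of the Gini index."""
    x = np.asarray(sizes, dtype=float)
    n = x.size
    return float(np.abs(x[:, None] - x[None, :]).sum() / (2.0 * n * n * x.mean()))


def hypergeom_two_sided_p(k: int, M: int, n: int, N: int) -> float:
    """Two-sided conditional exact p by direct pmf enumeration.

    ``k`` successes drawn, population ``M`` with ``n`` successes, draw size
    ``N``. Two-sided p sums all outcomes with pmf <= pmf(k) (the standard
    minimum-likelihood convention).
    """
    kk = np.arange(max(0, N - (M - n)), min(n, N) + 1)
    pmf = hypergeom.pmf(kk, M, n, N)
    p_obs = hypergeom.pmf(k, M, n, N)
    return float(pmf[pmf <= p_obs * (1 + 1e-12)].sum())
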