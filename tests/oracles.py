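"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths (and scipy's hypergeometric
tail) so that agreement is a genuine cross-check: exact integer enumeration
for Fisher tails, a literal step-up loop for BH, and concordant-pair counting
for AUC.
"""

from __future__ import annotations

import math

import numpy as np

_MAX_CACHED_N = 101
_COMB = [[math.comb(n, k) for k in range(_MAX_CACHED_N + 1)] for n in range(_MAX_CACHED_N + 1)]


def hypergeom_upper_tail(a: int, b: int, c: int, d: int) -> float:
    """Exact ``P(X >= a)`` of the 2x2 table by integer enumeration."""
    n_total = a + b + c + d
    k_col = a + c
    n_row = a + b
    num = 0
    if n_total <= _MAX_CACHED_N:
        row_k, row_nk = _COMB[k_col], _COMB[n_total - k_col]
        for i in range(a, min(n_row, k_col) + 1):
            num += row_k[i] * row_nk[n_row - i]
    else:
        for i in range(a, min(n_row, k_col) + 1):
            num += math.comb(k_col, i) * math.comb(n_total - k_col, n_row - i)
    return num / math.comb(n_total, n_row)


def bh_step_up(p_values) -> np.ndarray:
    """Literal Benjamini-Hochberg step-up definition."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        running = min(running, p[i] * m / (pos + 1))
        adj[i] = running
    return np.minimum(adj, 1.0)


def concordant_pair_auc(scores, labels) -> float:
    """AUC as the Mann-Whitney probability: concordant pairs / (n+ * n-),
    ties counted 1/2."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = s[y == 1]
    neg = s[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return float(wins) / (pos.size * neg.size)
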