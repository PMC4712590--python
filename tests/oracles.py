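"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations, structured differently from the library
code (per-pixel loops, full combinatorial enumeration) so agreement is
meaningful.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def brute_force_rgf(breast: np.ndarray, ft: np.ndarray) -> np.ndarray:
    """Per-pixel RGF oracle: classify every breast pixel of the slice by the
    annulus rule d in [r*R - 0.5, r*R + 0.5) for each of the 100 radii."""
    breast = np.asarray(breast) > 0
    ft = np.asarray(ft) > 0
    ys, xs = np.nonzero(breast)
    cy = sum(ys) / len(ys)
    cx = sum(xs) / len(xs)
    R = math.sqrt(len(ys) / math.pi)
    num = [0] * 100
    den = [0] * 100
    for y, x in zip(ys.tolist(), xs.tolist()):
        d = math.hypot(y - cy, x - cx)
        for k in range(1, 101):
            rho = (k / 100.0) * R
            if rho - 0.5 <= d < rho + 0.5:
                den[k - 1] += 1
                if ft[y, x]:
                    num[k - 1] += 1
    return np.array([n / d if d else np.nan for n, d in zip(num, den)])


def exact_rank_sum_p(a, b) -> float:
    """Two-sided Wilcoxon rank-sum p-value by full enumeration of all
    C(n1+n2, n1) assignments of the pooled ranks (assumes no ties)."""
    a, b = list(a), list(b)
    pooled = sorted(a + b)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n1 = len(a)
    w_obs = sum(ranks[v] for v in a)
    mean_w = n1 * (len(pooled) + 1) / 2.0
    dev_obs = abs(w_obs - mean_w)
    count = 0
    total = 0
    all_ranks = list(range(1, len(pooled) + 1))
    for combo in combinations(all_ranks, n1):
        total += 1
        if abs(sum(combo) - mean_w) >= dev_obs - 1e-9:
            count += 1
    return count / total
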