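"""Independently coded reference implementations used only by tests.

Each oracle is written as a direct, unvectorised transcription of the
statistic's definition, deliberately sharing no code with the package.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import hypergeom


def ssgsea_running_sum(values: dict[str, float], set_genes: set[str], alpha: float) -> float:
    """Walk the ranked gene list explicitly and accumulate the running sum."""
    ordered = sorted(values, key=lambda g: (-values[g], g))
    n = len(ordered)
    m = sum(1 for g in ordered if g in set_genes)
    total_in = 0.0
    for pos, gene in enumerate(ordered):  # position 0 is the top gene
        if gene in set_genes:
            total_in += abs(n - pos) ** alpha
    score = 0.0
    cum_in = 0.0
    cum_out = 0
    for pos, gene in enumerate(ordered):
        if gene in set_genes:
            cum_in += abs(n - pos) ** alpha
        else:
            cum_out += 1
        score += cum_in / total_in - cum_out / (n - m)
    return score


def auc_concordance(scores, labels) -> float:
    """O(n^2) pairwise concordance with 0.5 credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Sum of hypergeometric probabilities of tables at least as extreme
    (probability ordering), margins fixed."""
    r1, c1, n = a + b, a + c, a + b + c + d
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, r1, c1)
    p_obs = hypergeom.pmf(a, n, r1, c1)
    return float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())
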