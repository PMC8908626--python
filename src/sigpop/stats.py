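"""Rank and contingency statistics shared by the enrichment and DEG stages.

The Mann-Whitney / Wilcoxon machinery is implemented directly from the rank
formulas rather than delegated, because the enrichment rule depends on the
exact conventions (ties as half-wins, exact small-sample enumeration,
tie-corrected normal approximation with continuity correction). Tests compare
every branch against independent brute-force oracles.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = ["auc_from_labels", "rank_sum_test", "chi2_2x2", "EXACT_GROUP_MAX"]

# largest per-group size for which the exact permutation null is enumerated
EXACT_GROUP_MAX = 10


def auc_from_labels(scores, in_mask) -> float:
    """One-vs-rest ROC AUC computed exactly from rank statistics.

    AUC = P(in-score > out-score) + 0.5 * P(tie) = U / (n_in * n_out), where
    U is the Mann-Whitney statistic of the in-group.
    """
    scores = np.asarray(scores, dtype=float)
    in_mask = np.asarray(in_mask, dtype=bool)
    n1 = int(in_mask.sum())
    n2 = int((~in_mask).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("AUC undefined: in-group or out-group is empty")
    ranks = sps.rankdata(scores)
    u = ranks[in_mask].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n2))


def _exact_two_sided_p(ranks: np.ndarray, n1: int) -> float:
    """Enumerate all C(n, n1) group assignments of the observed (tied) ranks."""
    n = len(ranks)
    mu = n1 * (n - n1) / 2.0
    offset = n1 * (n1 + 1) / 2.0
    u_obs = ranks[:n1].sum() - offset
    dev = abs(u_obs - mu) - 1e-9  # float tolerance on half-integer rank sums
    hits = 0
    total = 0
    for combo in combinations(range(n), n1):
        u = ranks[list(combo)].sum() - offset
        total += 1
        if abs(u - mu) >= dev:
            hits += 1
    return hits / total


def rank_sum_test(x, y, exact_max: int = EXACT_GROUP_MAX) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (U, p).

    U is the Mann-Whitney statistic of ``x``. The p-value is computed by
    exact enumeration of all group assignments when both groups have at most
    ``exact_max`` observations (ties handled by enumerating the observed
    average ranks), and otherwise by the normal approximation with tie
    correction and a 0.5 continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("rank_sum_test requires two non-empty groups")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    if n1 <= exact_max and n2 <= exact_max:
        return u, _exact_two_sided_p(ranks, n1)
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3) - tie_counts).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all observations identical
        return u, 1.0
    mu = n1 * n2 / 2.0
    z = max(abs(u - mu) - 0.5, 0.0) / math.sqrt(var)
    p = min(1.0, 2.0 * sps.norm.sf(z))
    return u, p


def chi2_2x2(table, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-squared on a 2x2 table via the closed formula.

    Returns (chi2, p) on 1 degree of freedom. ``yates`` applies the
    continuity correction |ad - bc| -> max(|ad - bc| - N/2, 0).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("chi2_2x2 requires a 2x2 table")
    a, b = t[0]
    c, d = t[1]
    n = t.sum()
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    denom = r1 * r2 * c1 * c2
    if denom == 0:
        raise ValueError("degenerate 2x2 table: a zero margin")
    num = abs(a * d - b * c)
    if yates:
        num = max(num - n / 2.0, 0.0)
    chi2 = n * num**2 / denom
    return float(chi2), float(sps.chi2.sf(chi2, df=1))
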