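"""Independent brute-force / enumeration oracles used by the test suite.

These deliberately avoid the library code paths they check: rank-sum p by
full enumeration over group assignments, kNN/Jaccard/MNN by double loops,
quantiles by manual sort-and-interpolate.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.stats import rankdata


def exact_rank_sum_p(x, y) -> float:
    """Two-sided permutation p for the rank-sum statistic, midranks for ties.

    Enumerates all C(n1+n2, n1) assignments of the pooled midranks to the
    first group; p = fraction of assignments whose rank-sum deviates from
    its expectation at least as much as the observed one.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # midranks
    n1, n = len(x), len(pooled)
    expect = n1 * (n + 1) / 2.0
    obs = abs(ranks[:n1].sum() - expect)
    hits = total = 0
    for comb in combinations(range(n), n1):
        total += 1
        if abs(ranks[list(comb)].sum() - expect) >= obs - 1e-12:
            hits += 1
    return hits / total


def brute_knn_sets(points: np.ndarray, k: int) -> list[set[int]]:
    """k nearest points (self included), ties broken by index order."""
    n = len(points)
    sets = []
    for i in range(n):
        d = [(-1.0 if j == i else float(np.sum((points[i] - points[j]) ** 2)), j)
             for j in range(n)]
        d.sort()
        sets.append({j for _, j in d[:k]})
    return sets


def brute_snn_weights(points: np.ndarray, k: int, prune: float) -> np.ndarray:
    """Full Jaccard SNN weight matrix via enumerated neighbor sets."""
    sets = brute_knn_sets(points, k)
    n = len(points)
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            inter = len(sets[i] & sets[j])
            union = len(sets[i] | sets[j])
            w = inter / union
            W[i, j] = w if w > prune else 0.0
    return W


def brute_mnn_pairs(A: np.ndarray, B: np.ndarray, k: int) -> set[tuple[int, int]]:
    """Mutual k-nearest-neighbor cross pairs by double loop."""
    def knn(query, ref, kk):
        out = []
        for q in query:
            d = np.sum((ref - q) ** 2, axis=1)
            out.append(set(np.argsort(d, kind="stable")[:kk]))
        return out

    ab = knn(A, B, k)
    ba = knn(B, A, k)
    return {(i, j) for i in range(len(A)) for j in ab[i] if i in ba[j]}


def manual_quartiles(values) -> tuple[float, float, float]:
    """Type-7 (linear interpolation) quartiles by hand."""
    v = np.sort(np.asarray(values, float))
    n = len(v)

    def q(p: float) -> float:
        h = (n - 1) * p
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        return v[lo] + (h - lo) * (v[hi] - v[lo])

    return q(0.25), q(0.5), q(0.75)


def manual_pearson(a, b) -> tuple[float, float]:
    """Pearson r and two-sided p via the t-transform with n-2 df."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    a = a - a.mean()
    b = b - b.mean()
    r = float((a * b).sum() / np.sqrt((a**2).sum() * (b**2).sum()))
    n = len(a)
    if abs(r) >= 1.0:
        return r, 0.0
    tstat = r * np.sqrt((n - 2) / (1 - r**2))
    return r, float(2 * tdist.sf(abs(tstat), n - 2))
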