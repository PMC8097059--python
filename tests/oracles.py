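"""Independent brute-force oracles used to verify the package's statistics.

Each oracle follows the textbook definition literally (loops, exhaustive
enumeration, exact rational arithmetic where feasible) and shares no code
with the implementation it checks.
"""

from __future__ import annotations

from itertools import combinations
from math import comb, sqrt

import numpy as np


def bh_stepup(pvalues: list[float]) -> list[float]:
    """Textbook Benjamini–Hochberg step-up: sort, scale m·p/i, cummin from top."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    scaled = [pvalues[order[i]] * m / (i + 1) for i in range(m)]
    for i in range(m - 2, -1, -1):
        scaled[i] = min(scaled[i], scaled[i + 1])
    q = [0.0] * m
    for rank, idx in enumerate(order):
        q[idx] = min(scaled[rank], 1.0)
    return q


def hypergeom_tail(N: int, K: int, n: int, a: int) -> float:
    """Exact upper tail P(X >= a) for overlap of an n-draw with a K-set of N."""
    total = comb(N, n)
    acc = 0
    for k in range(a, min(K, n) + 1):
        acc += comb(K, k) * comb(N - K, n - k)
    return acc / total


def two_class_d(case: list[float], control: list[float], s0: float) -> float:
    """Moderated two-sample statistic by direct arithmetic."""
    n1, n2 = len(case), len(control)
    m1, m2 = sum(case) / n1, sum(control) / n2
    v1 = sum((x - m1) ** 2 for x in case) / (n1 - 1)
    v2 = sum((x - m2) ** 2 for x in control) / (n2 - 1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    se = sqrt(sp2 * (1 / n1 + 1 / n2))
    return (m1 - m2) / (se + s0)


def permutation_q(values: np.ndarray, n_case: int, s0: float) -> np.ndarray:
    """Exhaustive-permutation SAM q-values, looped from the definition.

    ``values`` is features × samples (first ``n_case`` columns are the
    observed case group).  All distinct case/control label splits except
    the observed one (and, for equal group sizes, its group swap, which
    reproduces the observed |d|) form the null set.  For each cutoff c (an
    observed |d|), the FDR is the mean over null splits of the number of
    permuted |d| >= c, divided by the number of observed |d| >= c; a
    feature's q is the minimum FDR over cutoffs it passes, capped at 1.
    """
    n_total = values.shape[1]
    d_obs = np.array([
        two_class_d(list(row[:n_case]), list(row[n_case:]), s0) for row in values
    ])
    abs_obs = np.abs(d_obs)

    skip = {tuple(range(n_case))}
    if n_total - n_case == n_case:
        skip.add(tuple(range(n_case, n_total)))
    perm_abs = []
    for split in combinations(range(n_total), n_case):
        if split in skip:
            continue
        rest = [i for i in range(n_total) if i not in split]
        d = [two_class_d([row[i] for i in split], [row[i] for i in rest], s0)
             for row in values]
        perm_abs.append(np.abs(d))
    perm_abs = np.array(perm_abs)

    q = np.empty(len(abs_obs))
    for i, di in enumerate(abs_obs):
        best = np.inf
        for c in abs_obs[abs_obs <= di]:
            R = int(np.sum(abs_obs >= c))
            V = float(np.mean(np.sum(perm_abs >= c, axis=1)))
            best = min(best, min(V / R, 1.0))
        q[i] = best
    return q


def anova_f(groups: list[list[float]]) -> float:
    """One-way ANOVA F from hand-computed sums of squares."""
    all_vals = [x for g in groups for x in g]
    grand = sum(all_vals) / len(all_vals)
    ss_between = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ss_within = sum(sum((x - sum(g) / len(g)) ** 2 for x in g) for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)


def ks_walk(query: set[str], ranking: list[str]) -> float:
    """Hand-stepped unweighted KS running sum; signed max deviation."""
    n, N = len(query), len(ranking)
    running, best = 0.0, 0.0
    for gene in ranking:
        running += 1.0 / n if gene in query else -1.0 / (N - n)
        if abs(running) > abs(best):
            best = running
    return best


def _partitions(items: list[int], k: int):
    """All partitions of items into exactly k non-empty unlabeled blocks."""
    if k == 1:
        yield [items]
        return
    if len(items) == k:
        yield [[i] for i in items]
        return
    head, rest = items[0], items[1:]
    for part in _partitions(rest, k):          # head joins an existing block
        for i in range(len(part)):
            yield part[:i] + [[head] + part[i]] + part[i + 1:]
    for part in _partitions(rest, k - 1):      # head forms its own block
        yield [[head]] + part


def best_kmeans_partition(X: np.ndarray, k: int) -> tuple[float, list[list[int]]]:
    """Global within-cluster sum of squares optimum by exhaustive partition search."""
    best_ss, best_part = np.inf, None
    for part in _partitions(list(range(len(X))), k):
        ss = 0.0
        for block in part:
            centroid = X[block].mean(axis=0)
            ss += float(((X[block] - centroid) ** 2).sum())
        if ss < best_ss:
            best_ss, best_part = ss, [sorted(b) for b in part]
    return best_ss, best_part


def average_linkage_merges(dist: np.ndarray) -> list[tuple[frozenset, float]]:
    """Naive average-linkage agglomeration: (merged member set, height) list."""
    n = dist.shape[0]
    clusters: dict[int, frozenset] = {i: frozenset([i]) for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a, b in combinations(sorted(clusters), 2):
            ca, cb = clusters[a], clusters[b]
            d = np.mean([dist[i, j] for i in ca for j in cb])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        merged = clusters.pop(a) | clusters.pop(b)
        clusters[next_id] = merged
        merges.append((merged, d))
        next_id += 1
    return merges
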