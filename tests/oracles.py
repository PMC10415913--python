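"""Independent brute-force oracles used to validate the package.

Everything here is deliberately naive (enumeration, direct recursion,
textbook formulas) and shares no code with the implementation under
test.
"""

from __future__ import annotations

import itertools

import numpy as np


def bh_adjust(p):
    """Brute-force Benjamini-Hochberg: adj_i = min over j with
    p_j >= p_i of min(1, n * p_j / rank_j)."""
    p = list(map(float, p))
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adjusted = [0.0] * n
    running_min = 1.0
    for pos in range(n - 1, -1, -1):
        i = order[pos]
        running_min = min(running_min, p[i] * n / (pos + 1))
        adjusted[i] = min(running_min, 1.0)
    return adjusted


def frequent_itemsets_powerset(transactions, min_support, max_size=None):
    """All frequent item sets by explicit powerset enumeration.

    Returns {frozenset: support_fraction}.
    """
    items = sorted({it for tx in transactions for it in tx})
    n = len(transactions)
    if max_size is None:
        max_size = len(items)
    out = {}
    for size in range(1, max_size + 1):
        for combo in itertools.combinations(items, size):
            s = frozenset(combo)
            count = sum(1 for tx in transactions if s <= tx)
            support = count / n
            if support >= min_support - 1e-12:
                out[s] = support
    return out


def rules_bruteforce(transactions, min_support, max_size=None):
    """All rules (every bipartition of every frequent set of size >= 2)
    with support/confidence/lift from direct contingency counting."""
    n = len(transactions)
    freq = frequent_itemsets_powerset(transactions, min_support, max_size)
    rules = {}
    for itemset in freq:
        if len(itemset) < 2:
            continue
        for r in range(1, len(itemset)):
            for a in itertools.combinations(sorted(itemset), r):
                a = frozenset(a)
                b = itemset - a
                count_ab = sum(1 for tx in transactions if itemset <= tx)
                count_a = sum(1 for tx in transactions if a <= tx)
                count_b = sum(1 for tx in transactions if b <= tx)
                support = count_ab / n
                confidence = count_ab / count_a
                lift = confidence / (count_b / n)
                rules[(a, b)] = (support, confidence, lift)
    return rules


def floyd_warshall(n, edges):
    """All-pairs shortest distances on an undirected weighted graph
    given as {(i, j): w}; unreachable pairs stay inf."""
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for (i, j), w in edges.items():
        dist[i, j] = min(dist[i, j], w)
        dist[j, i] = min(dist[j, i], w)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    return dist


def dbv_ordered_pair_sum(pairs_values, n_genes):
    """The per-set threshold as an explicit ordered-pair sum divided by
    2 and by the number of unordered pairs."""
    ngp = n_genes * (n_genes - 1) // 2
    total = sum(pairs_values) * 2  # ordered pairs double-count each value
    return total / 2 / ngp


def pooled_t_stats(matrix, labels):
    """Ordinary pooled two-sample t per row (textbook formula)."""
    g1 = matrix[:, labels == 1]
    g0 = matrix[:, labels == 0]
    n1, n0 = g1.shape[1], g0.shape[1]
    sp2 = (
        g1.var(axis=1, ddof=1) * (n1 - 1) + g0.var(axis=1, ddof=1) * (n0 - 1)
    ) / (n1 + n0 - 2)
    se = np.sqrt(sp2 * (1 / n1 + 1 / n0))
    return (g1.mean(axis=1) - g0.mean(axis=1)) / se
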