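"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (enumeration, direct definitions) and
shares no code with the implementation under test.
"""

from itertools import combinations

import numpy as np


def bh_stepup(p):
    """Benjamini-Hochberg step-up straight from the definition."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    adj = np.empty(m)
    running = np.inf
    for i in range(m - 1, -1, -1):
        running = min(running, sorted_p[i] * m / (i + 1))
        adj[i] = min(running, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def set_partitions(items):
    """All partitions of a list into non-empty blocks (Bell-number many)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] + [first]] + part[i + 1 :]
        yield part + [[first]]


def graph_modularity(weights: np.ndarray, blocks) -> float:
    """Q from the definition on a symmetric weight matrix."""
    m2 = weights.sum()  # counts each edge twice
    deg = weights.sum(axis=1)
    q = 0.0
    for block in blocks:
        idx = np.asarray(block)
        q += weights[np.ix_(idx, idx)].sum() / m2 - (deg[idx].sum() / m2) ** 2
    return q


def max_modularity_exhaustive(weights: np.ndarray):
    """Best (Q, partition) over every partition of the node set."""
    n = weights.shape[0]
    best_q, best_part = -np.inf, None
    for part in set_partitions(range(n)):
        q = graph_modularity(weights, part)
        if q > best_q:
            best_q, best_part = q, part
    return best_q, best_part


def spearman_permutation_p(x, y, n_perm=20_000, seed=0):
    """Permutation p-value for Spearman's rho by shuffling one variable."""
    from scipy.stats import spearmanr

    rng = np.random.default_rng(seed)
    obs = abs(spearmanr(x, y).statistic)
    y = np.asarray(y)
    hits = 0
    for _ in range(n_perm):
        if abs(spearmanr(x, rng.permutation(y)).statistic) >= obs - 1e-12:
            hits += 1
    return hits / n_perm


def adjusted_rand_index(labels_a, labels_b) -> float:
    """ARI from the contingency-table definition."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    n = a.size
    classes_a, classes_b = np.unique(a), np.unique(b)
    table = np.array([[np.sum((a == ca) & (b == cb)) for cb in classes_b] for ca in classes_a])
    comb2 = lambda x: x * (x - 1) / 2.0
    sum_ij = comb2(table).sum()
    sum_a = comb2(table.sum(axis=1)).sum()
    sum_b = comb2(table.sum(axis=0)).sum()
    expected = sum_a * sum_b / comb2(n)
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)
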