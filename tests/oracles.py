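"""Independent brute-force reference implementations used only by tests.

Each oracle recomputes a quantity from first principles (exhaustive
enumeration, pair counting) without touching the library's code paths, so
agreement is evidence of correctness rather than of shared bugs.
"""

from itertools import combinations, permutations
from math import comb

import numpy as np


def brute_shortest_paths(weights, norm_weight=None):
    """All-pairs shortest path lengths by enumerating every simple path."""
    n = weights.shape[0]
    if norm_weight is None:
        norm_weight = weights.max()
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    nodes = range(n)
    for src in nodes:
        for dst in nodes:
            if src == dst:
                continue
            best = np.inf
            others = [v for v in nodes if v not in (src, dst)]
            for r in range(len(others) + 1):
                for mid in permutations(others, r):
                    path = (src, *mid, dst)
                    total = 0.0
                    ok = True
                    for a, b in zip(path, path[1:]):
                        if weights[a, b] <= 0:
                            ok = False
                            break
                        total += norm_weight / weights[a, b]
                    if ok:
                        best = min(best, total)
            dist[src, dst] = best
    return dist


def brute_global_efficiency(weights, norm_weight=None):
    """GE from the enumerated distance matrix; 1/inf counts as 0."""
    n = weights.shape[0]
    if norm_weight is None:
        norm_weight = weights.max()
    if norm_weight <= 0:
        return 0.0
    dist = brute_shortest_paths(weights, norm_weight)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(dist[i, j]):
                total += 1.0 / dist[i, j]
    return total / (n * (n - 1))


def brute_auc(scores, y):
    """P(score_pos > score_neg) + 0.5 P(equal) by exhaustive pair counting."""
    pos = [s for s, label in zip(scores, y) if label == 1]
    neg = [s for s, label in zip(scores, y) if label == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else 0.5 if p == q else 0.0
    return total / (len(pos) * len(neg))


def brute_ranksum_p(x, y):
    """Exact two-sided rank-sum p by enumerating all C(nx+ny, nx) labelings."""
    pooled = sorted(list(x) + list(y))
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    nx = len(x)
    n = len(pooled)
    w_obs = sum(ranks[v] for v in x)
    mu = nx * (n + 1) / 2
    dev = abs(w_obs - mu)
    hits = 0
    for subset in combinations(range(1, n + 1), nx):
        if abs(sum(subset) - mu) >= dev - 1e-9:
            hits += 1
    return hits / comb(n, nx)
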