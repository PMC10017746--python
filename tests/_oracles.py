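"""Independent brute-force oracles used to check the implementation.

These deliberately avoid the code paths under test: shortest paths by
exhaustive simple-path enumeration and by a literal Floyd-Warshall triple
loop, efficiency by direct summation over the enumerated distances, AUC by
counting concordant pairs.
"""

from itertools import permutations

import numpy as np


def exhaustive_shortest_paths(direct: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths by enumerating every simple path (n small)."""
    direct = np.asarray(direct, dtype=float)
    n = direct.shape[0]
    out = np.full((n, n), np.inf)
    np.fill_diagonal(out, 0.0)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            best = direct[i, j]
            others = [k for k in range(n) if k not in (i, j)]
            for r in range(1, len(others) + 1):
                for mids in permutations(others, r):
                    path = (i, *mids, j)
                    length = sum(direct[a, b] for a, b in zip(path[:-1], path[1:]))
                    best = min(best, length)
            out[i, j] = best
    return out


def floyd_warshall(direct: np.ndarray) -> np.ndarray:
    d = np.asarray(direct, dtype=float).copy()
    n = d.shape[0]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def efficiency_from_distances(d: np.ndarray) -> float:
    n = d.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]) and d[i, j] > 0:
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def brute_auc(scores, labels) -> float:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (pos.size * neg.size)
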