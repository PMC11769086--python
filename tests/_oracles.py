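"""Independent brute-force oracles used by the test suite.

The flexible-beta oracle keeps every cluster as an explicit binary merge
tree and evaluates inter-cluster distances by recursive expansion of the
Lance-Williams recurrence (gamma = 0, alpha_i = alpha_j = (1-beta)/2),
re-scanning all cluster pairs from scratch at every step.  Because the
recurrence defines the distance to a *newly formed* cluster in terms of its
two parents, the recursion must always expand the more recently formed of
the two clusters; each merge node therefore carries its formation step.
"""

from __future__ import annotations

import numpy as np

# a cluster is either an int (leaf site) or a tuple (left, right, step)


def _step(t) -> int:
    return -1 if isinstance(t, int) else t[2]


def _tree_distance(t1, t2, D, alpha, beta, memo):
    key = (t1, t2)
    if key in memo:
        return memo[key]
    if isinstance(t1, int) and isinstance(t2, int):
        d = D[t1, t2]
    else:
        # expand whichever cluster was formed later
        if _step(t1) < _step(t2):
            t1, t2 = t2, t1
        left, right, _ = t1
        d = (alpha * (_tree_distance(left, t2, D, alpha, beta, memo)
                      + _tree_distance(right, t2, D, alpha, beta, memo))
             + beta * _tree_distance(left, right, D, alpha, beta, memo))
    memo[key] = d
    return d


def brute_force_flexible_beta(D: np.ndarray, beta: float,
                              n_groups: int) -> np.ndarray:
    """Labels from naive flexible-beta agglomeration, ties resolved toward
    the pair whose smallest original member indices compare
    lexicographically smaller (matching the convention under test)."""
    n = D.shape[0]
    alpha = (1.0 - beta) / 2.0
    clusters: list = list(range(n))
    memo: dict = {}

    def leader(t):
        return t if isinstance(t, int) else min(leader(t[0]), leader(t[1]))

    step = 0
    while len(clusters) > n_groups:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = _tree_distance(clusters[i], clusters[j], D, alpha, beta, memo)
                cand = (d, leader(clusters[i]), leader(clusters[j]))
                if best is None or cand < best[0]:
                    best = (cand, i, j)
        _, i, j = best
        merged = (clusters[i], clusters[j], step)
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
        step += 1

    def members(t):
        return [t] if isinstance(t, int) else members(t[0]) + members(t[1])

    labels = np.empty(n, dtype=int)
    for g, tree in enumerate(sorted(clusters, key=leader)):
        labels[members(tree)] = g
    return labels


def same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    """True when two label vectors induce the same partition."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        return False
    return len({(x, y) for x, y in zip(a, b)}) == len(set(a)) == len(set(b))
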