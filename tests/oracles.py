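"""Independent brute-force oracles used by the test suite.

These deliberately re-implement the algorithms in plain Python loops,
straight from their definitions, sharing no code with the package.
"""

from __future__ import annotations

import math

import numpy as np


def brute_force_distances(X, metric):
    """Element-by-element dissimilarity loop, straight from the formulas."""
    n = len(X)
    D = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if metric == "euclidean":
                D[i][j] = math.sqrt(sum((a - b) ** 2 for a, b in zip(X[i], X[j])))
            elif metric == "manhattan":
                D[i][j] = sum(abs(a - b) for a, b in zip(X[i], X[j]))
            elif metric == "cosine":
                ni = math.sqrt(sum(a * a for a in X[i]))
                nj = math.sqrt(sum(b * b for b in X[j]))
                if ni == 0 and nj == 0:
                    D[i][j] = 0.0
                elif ni == 0 or nj == 0:
                    D[i][j] = 1.0
                else:
                    dot = sum(a * b for a, b in zip(X[i], X[j]))
                    D[i][j] = max(0.0, 1.0 - dot / (ni * nj))
    return np.array(D)


def mdgraph_edges_oracle(D, caps, t0, delta, max_val):
    """Literal walk/refine construction on a distance matrix.

    ``caps`` is a per-node list of neighbor caps (class-specific caps are
    resolved by the caller).  Returns (adjacency as a set of frozensets,
    initiated counts, final t).  Walk order is ascending distance with ties
    broken by ascending index; a node's walk counts every accepted
    candidate; refinement raises a shared t by delta at most 5 times, then
    clamps to the matrix maximum.
    """
    n = len(D)
    edges: set[frozenset] = set()
    counts = [0] * n
    accepted = [set() for _ in range(n)]

    def walk(i, t):
        order = sorted((j for j in range(n) if j != i), key=lambda j: (D[i][j], j))
        for j in order:
            if counts[i] >= caps[i]:
                break
            if D[i][j] > t:
                break
            if j in accepted[i]:
                continue
            edges.add(frozenset((i, j)))
            accepted[i].add(j)
            counts[i] += 1

    for i in range(n):
        walk(i, t0)

    t = t0
    increments = 0
    for i in [v for v in range(n) if counts[v] < caps[v]]:
        while counts[i] < caps[i] and increments < 5:
            t += delta
            increments += 1
            if increments == 5:
                t = max(t, max_val)
            walk(i, t)
        if counts[i] < caps[i] and increments >= 5:
            walk(i, t)
    return edges, counts, t


def adaboost_scalar_oracle(patterns, n, floor=1e-10):
    """Scalar AdaBoost trace given per-attempt misclassification patterns.

    ``patterns`` is the sequence of boolean misclassification vectors the
    base learners produce, in attempt order.  Returns the kept rounds'
    (epsilon, alpha) and the weight trajectory, applying the discard rule
    at weighted error >= 0.5.
    """
    w = [1.0 / n] * n
    kept = []
    trace = []
    for mis in patterns:
        eps = sum(wi for wi, m in zip(w, mis) if m) / sum(w)
        if eps >= 0.5:
            continue
        eps_c = min(max(eps, floor), 1 - floor)
        alpha = 0.5 * math.log((1 - eps_c) / eps_c)
        w = [wi * math.exp(alpha if m else -alpha) for wi, m in zip(w, mis)]
        total = sum(w)
        w = [wi / total for wi in w]
        kept.append((eps, alpha))
        trace.append(list(w))
    return kept, trace


def auc_pairwise_oracle(y, s):
    """AUC as the fraction of concordant (sick, healthy) pairs, ties = 1/2."""
    pos = [si for yi, si in zip(y, s) if yi == 1]
    neg = [si for yi, si in zip(y, s) if yi == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def nearest_centroid_accuracy(X_train, y_train, X_test, y_test):
    """Brute-force nearest-centroid classification accuracy."""
    c0 = X_train[y_train == 0].mean(axis=0)
    c1 = X_train[y_train == 1].mean(axis=0)
    pred = [
        1 if np.linalg.norm(x - c1) < np.linalg.norm(x - c0) else 0 for x in X_test
    ]
    return float(np.mean(np.array(pred) == y_test))
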