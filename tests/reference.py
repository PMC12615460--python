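"""Brute-force reference implementations of the selection strategies.

Deliberately written as plain python loops, independent of the package's
vectorized implementations, to serve as oracles in tests.
"""

import math
from itertools import combinations

import numpy as np


def dist(a, b):
    return math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))


def brute_top(Z, pool, centers, assign):
    """Nearest actual member per cluster, given a fitted k-means result.

    ``pool`` maps rows of the clustered subset back to dataset indices;
    clusters are visited in id order, ties toward the lowest dataset index.
    """
    chosen = []
    for c in range(len(centers)):
        best, best_d = None, None
        for row, a in enumerate(assign):
            if a != c:
                continue
            d = dist(Z[pool[row]], centers[c])
            if best_d is None or d < best_d:
                best, best_d = pool[row], d
        if best is not None:
            chosen.append(int(best))
    return chosen


def brute_coreset(Z, labeled, pool, k):
    """Greedy farthest-first traversal with the max-norm-from-mean bootstrap."""
    labeled = list(labeled)
    pool = [int(i) for i in pool]
    chosen = []
    if not labeled:
        center = np.mean(Z, axis=0)
        best, best_d = None, -1.0
        for i in pool:
            d = dist(Z[i], center)
            if d > best_d:
                best, best_d = i, d
        chosen.append(best)
    while len(chosen) < k:
        anchors = labeled + chosen
        best, best_d = None, -1.0
        for i in pool:
            if i in chosen:
                continue
            d = min(dist(Z[i], Z[j]) for j in anchors)
            if d > best_d:
                best, best_d = i, d
        chosen.append(best)
    return chosen


def brute_mi(probs, pool, k):
    """Sort by top-1 minus top-2 posterior margin, ties toward lowest index."""
    scored = []
    for row, i in enumerate(pool):
        p = sorted(probs[row], reverse=True)
        scored.append((p[0] - p[1], int(i)))
    scored.sort()
    return [i for _, i in scored[:k]]


def cover_radius(Z, pool, centers_idx):
    """Max over the pool of the distance to its nearest chosen center."""
    return max(min(dist(Z[i], Z[j]) for j in centers_idx) for i in pool)


def optimal_kcenter_radius(Z, pool, k):
    """Exhaustive search over all k-subsets of the pool (tiny instances)."""
    best = math.inf
    for subset in combinations(pool, k):
        best = min(best, cover_radius(Z, pool, subset))
    return best


def chi_reference(points, labels):
    """Calinski-Harabasz from the textbook formula, plain loops."""
    points = np.asarray(points, dtype=float)
    ks = sorted(set(int(l) for l in labels))
    N = len(points)
    mu = points.mean(axis=0)
    B = W = 0.0
    for c in ks:
        members = points[np.asarray(labels) == c]
        muc = members.mean(axis=0)
        B += len(members) * float(((muc - mu) ** 2).sum())
        W += float(((members - muc) ** 2).sum())
    k = len(ks)
    return (B / (k - 1)) / (W / (N - k))


def dbi_reference(points, labels):
    """Davies-Bouldin from the textbook formula, plain loops."""
    points = np.asarray(points, dtype=float)
    ks = sorted(set(int(l) for l in labels))
    mus, Ss = [], []
    for c in ks:
        members = points[np.asarray(labels) == c]
        muc = members.mean(axis=0)
        mus.append(muc)
        Ss.append(float(np.mean([dist(x, muc) for x in members])))
    total = 0.0
    for i in range(len(ks)):
        worst = -math.inf
        for j in range(len(ks)):
            if i == j:
                continue
            worst = max(worst, (Ss[i] + Ss[j]) / dist(mus[i], mus[j]))
        total += worst
    return total / len(ks)
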