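"""Independent reference implementations used to cross-check the package.

These are deliberately naive (exhaustive enumeration, quadratic recomputation)
so that any agreement with the fast implementations is meaningful.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations

import numpy as np


def dtw_bruteforce(a: np.ndarray, b: np.ndarray, window_frac: float) -> float:
    """Minimum path cost over all monotone warping paths (exhaustive).

    Mirrors the package's admissibility rule: cell (i, j) is usable iff
    |i*(m-1) - j*(n-1)| <= ceil(window_frac * max(n, m)) * max(n-1, m-1).
    Returns inf when no admissible path exists.
    """
    a = np.atleast_2d(np.asarray(a, float))
    b = np.atleast_2d(np.asarray(b, float))
    if a.shape[0] == 1 and a.shape[1] > 1 and b.shape[0] != 1:
        pass
    n, m = a.shape[0], b.shape[0]
    band = int(np.ceil(window_frac * max(n, m)))
    lim = band * max(n - 1, m - 1)

    def ok(i: int, j: int) -> bool:
        return abs(i * (m - 1) - j * (n - 1)) <= lim

    def cost(i: int, j: int) -> float:
        return float(np.sqrt(((a[i] - b[j]) ** 2).sum()))

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> float:
        if not ok(i, j):
            return np.inf
        if i == 0 and j == 0:
            return cost(0, 0)
        prev = np.inf
        if i > 0 and j > 0:
            prev = min(prev, best(i - 1, j - 1))
        if i > 0:
            prev = min(prev, best(i - 1, j))
        if j > 0:
            prev = min(prev, best(i, j - 1))
        return cost(i, j) + prev

    return best(n - 1, m - 1)


def greedy_ward_partitions(dm: np.ndarray) -> list[set[frozenset[int]]]:
    """From-scratch greedy Ward agglomeration on a distance matrix.

    At each step the pair of clusters with the smallest increase of the
    within-cluster sum of squared distances is merged, where the increase is
    computed from first principles on the squared input distances:

        delta(A, B) = |A||B|/(|A|+|B|) * (M_AB - M_AA/2 - M_BB/2)

    with M_XY the mean of squared distances over all ordered (x, y) pairs.
    Returns the partition sequence from n singletons down to one cluster;
    entry [n - k] is the k-cluster partition.
    """
    n = dm.shape[0]
    d2 = np.asarray(dm, float) ** 2

    def mean_sq(A: frozenset[int], B: frozenset[int]) -> float:
        return float(d2[np.ix_(sorted(A), sorted(B))].mean())

    clusters = [frozenset([i]) for i in range(n)]
    parts = [set(clusters)]
    while len(clusters) > 1:
        best = None
        for ia, ib in combinations(range(len(clusters)), 2):
            A, B = clusters[ia], clusters[ib]
            delta = (len(A) * len(B) / (len(A) + len(B))) * (
                mean_sq(A, B) - mean_sq(A, A) / 2.0 - mean_sq(B, B) / 2.0
            )
            if best is None or delta < best[0]:
                best = (delta, ia, ib)
        _, ia, ib = best
        merged = clusters[ia] | clusters[ib]
        clusters = [c for i, c in enumerate(clusters) if i not in (ia, ib)]
        clusters.append(merged)
        parts.append(set(clusters))
    return parts


def partition_of(labels: np.ndarray) -> set[frozenset[int]]:
    """Label vector -> label-free partition (set of index sets)."""
    labels = np.asarray(labels)
    return {
        frozenset(int(i) for i in np.flatnonzero(labels == c))
        for c in np.unique(labels)
    }
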