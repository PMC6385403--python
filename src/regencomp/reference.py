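"""Naive reference implementations used for cross-validation.

These deliberately avoid the optimized code paths used by the package proper:
the hypergeometric tail is a direct log-space summation, the linkage oracle is
a greedy agglomerator that recomputes every merge cost from the raw cluster
members, and the Mann-Whitney oracle enumerates group assignments. They exist
so that the fast implementations can be checked against an independent route,
both in the test suite and in the acceptance script.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.special import gammaln, logsumexp


def hypergeom_tail_logp(k: int, n1: int, n2: int, N: int) -> float:
    """log P[X >= k] for X ~ Hypergeometric(N, n1, n2), by direct summation."""

    def log_comb(n, r):
        return gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)

    hi = min(n1, n2)
    lo = max(k, n1 + n2 - N, 0)
    if lo > hi:
        return -np.inf
    i = np.arange(lo, hi + 1)
    terms = log_comb(n1, i) + log_comb(N - n1, n2 - i) - log_comb(N, n2)
    return float(logsumexp(terms))


def greedy_linkage(points: np.ndarray, method: str) -> list[tuple[frozenset, frozenset, float]]:
    """Agglomerate by recomputing inter-cluster costs from members each step.

    ``method`` is ``"average"`` (UPGMA: mean pairwise Euclidean distance) or
    ``"ward2"`` (cost = sqrt of twice the increase in total within-cluster sum
    of squares). Returns the merge sequence as (cluster_a, cluster_b, height)
    with clusters given as frozensets of leaf indices.
    """
    points = np.asarray(points, dtype=float)
    clusters: list[frozenset] = [frozenset([i]) for i in range(len(points))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            ca, cb = clusters[a], clusters[b]
            if method == "average":
                d = np.mean([
                    np.linalg.norm(points[i] - points[j]) for i in ca for j in cb
                ])
            elif method == "ward2":
                pa = points[sorted(ca)]
                pb = points[sorted(cb)]
                pm = np.vstack([pa, pb])
                ss = lambda m: np.sum((m - m.mean(axis=0)) ** 2)
                d = np.sqrt(2.0 * (ss(pm) - ss(pa) - ss(pb)))
            else:
                raise ValueError(f"unknown method {method!r}")
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        merges.append((clusters[a], clusters[b], float(d)))
        merged = clusters[a] | clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)]
        clusters.append(merged)
    return merges


def mwu_exact_p(x, y) -> tuple[float, float]:
    """(U, two-sided p) of the Mann-Whitney test by full enumeration.

    Enumerates every way of labelling the pooled observations as group x,
    computes U_x for each (with 0.5 credit for ties), and doubles the lower
    tail of min(U_x, U_y), capping at 1.
    """
    x = list(x)
    y = list(y)
    pooled = x + y
    n, m = len(x), len(y)

    def u_of(xs, ys):
        return sum(
            1.0 if xi > yi else (0.5 if xi == yi else 0.0) for xi in xs for yi in ys
        )

    u_obs = min(u_of(x, y), u_of(y, x))
    count = total = 0
    for idx in itertools.combinations(range(n + m), n):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n + m) if i not in idx]
        if u_of(xs, ys) <= u_obs:
            count += 1
        total += 1
    return u_obs, min(1.0, 2.0 * count / total)


def pairwise_distances_loop(rows: np.ndarray) -> np.ndarray:
    """Double-loop Euclidean distance matrix (oracle for the fast path)."""
    rows = np.asarray(rows, dtype=float)
    n = len(rows)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = np.sqrt(np.sum((rows[i] - rows[j]) ** 2))
    return out
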