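"""Independent brute-force oracles used by the test suite.

Each oracle is a deliberately naive reimplementation (sliding windows,
exhaustive dynamic programming, exact integer hypergeometric sums, direct
agglomeration) kept free of the code paths it checks.
"""

from __future__ import annotations

import math
from fractions import Fraction
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np


def brute_scan(seq: str, allowed_sets: Sequence[Set[str]]) -> List[int]:
    """Sliding-window exact matching of a degenerate pattern."""
    seq = seq.upper()
    k = len(allowed_sets)
    return [
        i
        for i in range(len(seq) - k + 1)
        if all(seq[i + j] in allowed_sets[j] for j in range(k))
    ]


def gotoh_score(
    s1: str,
    s2: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -0.5,
    gap_extend: float = -0.1,
) -> float:
    """Quadratic-time affine-gap global alignment score (end gaps penalized).

    A gap of length L costs gap_open + (L-1)*gap_extend; insertions may sit
    next to deletions.
    """
    n, m = len(s1), len(s2)
    NEG = -math.inf
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in s2 (consume s1)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in s1 (consume s2)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(n + 1):
        for j in range(m + 1):
            if i > 0 and j > 0:
                s = match if s1[i - 1] == s2[j - 1] else mismatch
                M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            if i > 0:
                cand = max(
                    M[i - 1][j] + gap_open,
                    X[i - 1][j] + gap_extend,
                    Y[i - 1][j] + gap_open,
                )
                X[i][j] = max(X[i][j], cand)
            if j > 0:
                cand = max(
                    M[i][j - 1] + gap_open,
                    Y[i][j - 1] + gap_extend,
                    X[i][j - 1] + gap_open,
                )
                Y[i][j] = max(Y[i][j], cand)
    return max(M[n][m], X[n][m], Y[n][m])


def fisher_enum(a: int, b: int, c: int, d: int, direction: str = "greater") -> float:
    """Exact one-sided Fisher p by summing hypergeometric point masses.

    Uses exact integer binomials and one rational division, so the result
    is correct to float rounding.
    """
    N = a + b + c + d
    K = a + c  # property margin
    n = a + b  # set margin
    lo = max(0, n - (N - K))
    hi = min(n, K)
    if direction == "greater":
        ks = range(a, hi + 1)
    elif direction == "less":
        ks = range(lo, a + 1)
    else:
        raise ValueError(direction)
    num = sum(math.comb(K, k) * math.comb(N - K, n - k) for k in ks)
    return float(Fraction(num, math.comb(N, n)))


def bh_reference(pvalues: Sequence[float]) -> np.ndarray:
    """Direct (quadratic) evaluation of the BH step-up q-value definition."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order, start=1):
        candidates = [
            m * p[order[j - 1]] / j for j in range(rank_pos, m + 1)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


def brute_agglomerate(D: np.ndarray, method: str) -> List[Tuple[frozenset, float]]:
    """Naive agglomeration; returns (merged leaf set, height) per merge.

    ``average``: inter-cluster distance is the mean over member pairs of the
    original distances.  ``ward``: Lance-Williams update on Euclidean
    distances between observations (D must be the pairwise Euclidean matrix).
    """
    n = D.shape[0]
    clusters: Dict[int, frozenset] = {i: frozenset([i]) for i in range(n)}
    dist: Dict[Tuple[int, int], float] = {
        (i, j): float(D[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    merges = []
    next_id = n
    while len(clusters) > 1:
        (i, j), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        ci, cj = clusters.pop(i), clusters.pop(j)
        merged = ci | cj
        merges.append((merged, h))
        new_dist = {}
        for k, ck in clusters.items():
            a, b = (i, k) if i < k else (k, i)
            dik = dist[(a, b)]
            a, b = (j, k) if j < k else (k, j)
            djk = dist[(a, b)]
            if method == "average":
                new = (len(ci) * dik + len(cj) * djk) / (len(ci) + len(cj))
            elif method == "ward":
                ni, nj, nk = len(ci), len(cj), len(ck)
                new = math.sqrt(
                    ((ni + nk) * dik**2 + (nj + nk) * djk**2 - nk * h**2)
                    / (ni + nj + nk)
                )
            else:
                raise ValueError(method)
            new_dist[(k, next_id) if k < next_id else (next_id, k)] = new
        dist = {
            key: v
            for key, v in dist.items()
            if i not in key and j not in key
        }
        dist.update(new_dist)
        clusters[next_id] = merged
        next_id += 1
    return merges


def linkage_to_leafsets(Z: np.ndarray) -> List[Tuple[frozenset, float]]:
    """scipy linkage -> (leaf set, height) per merge, for tree comparison."""
    n = Z.shape[0] + 1
    sets: Dict[int, frozenset] = {i: frozenset([i]) for i in range(n)}
    out = []
    for k, row in enumerate(Z):
        merged = sets[int(row[0])] | sets[int(row[1])]
        sets[n + k] = merged
        out.append((merged, float(row[2])))
    return out
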