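"""Independent reference implementations used only by the test suite.

Everything here is deliberately written the slow, obvious way, using exact
integer arithmetic where possible, and shares no code with the package.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


def hypergeom_pmf_exact(k: int, K: int, n: int, N: int) -> Fraction:
    """Exact rational hypergeometric point probability via math.comb."""
    if k < 0 or k > n or k > K or n - k > N - K:
        return Fraction(0)
    return Fraction(math.comb(K, k) * math.comb(N - K, n - k), math.comb(N, n))


def fisher_greater_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """One-sided Fisher p by exhaustive enumeration over the full support."""
    N = a + b + c + d
    n_sel, K = a + b, a + c
    total = Fraction(0)
    for x in range(0, min(n_sel, K) + 1):
        if x >= a:
            total += hypergeom_pmf_exact(x, K, n_sel, N)
    return total


def bh_adjust_reference(pvalues: list[float]) -> list[float]:
    """Textbook step-up BH: adj_i = min over j with p_j >= p_i of
    min(1, m * p_j / rank_j), ranks from the sorted order."""
    m = len(pvalues)
    indexed = sorted(range(m), key=lambda i: pvalues[i])
    out = [0.0] * m
    for pos, i in enumerate(indexed):
        candidates = [
            min(1.0, m * pvalues[j] / (qpos + 1))
            for qpos, j in enumerate(indexed)
            if qpos >= pos
        ]
        out[i] = min(candidates)
    return out


def bonferroni_reference(pvalues: list[float]) -> list[float]:
    return [min(1.0, len(pvalues) * p) for p in pvalues]


def agglomerate_reference(D: np.ndarray, linkage: str) -> list[tuple[int, int, float]]:
    """Naive agglomeration recomputing inter-cluster distances from the
    original pairwise matrix at every step (single/complete/average only).

    Returns (left_node, right_node, height) triples with the same node
    numbering convention as the package: leaves 0..n-1, merges n, n+1, ...
    Tie-break: lowest (min original leaf, then the other cluster's min leaf).
    """
    n = D.shape[0]
    clusters: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        ids = list(clusters)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                ci, cj = ids[i], ids[j]
                pair_d = [D[p, q] for p in clusters[ci] for q in clusters[cj]]
                if linkage == "single":
                    d = min(pair_d)
                elif linkage == "complete":
                    d = max(pair_d)
                elif linkage == "average":
                    d = sum(pair_d) / len(pair_d)
                else:
                    raise ValueError(linkage)
                a, b = sorted((ci, cj), key=lambda c: min(clusters[c]))
                key = (d, min(clusters[a]), min(clusters[b]))
                if best is None or key < best[0]:
                    best = (key, a, b, d)
        _, a, b, d = best
        merges.append((a, b, float(d)))
        clusters[next_id] = clusters.pop(a) | clusters.pop(b)
        next_id += 1
    return merges


def pca_eigh_reference(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """PCA via eigendecomposition of the covariance matrix.

    Returns (eigenvalues descending, scores) with arbitrary per-component
    sign; callers align signs before comparing.
    """
    Xc = X - X.mean(axis=0, keepdims=True)
    cov = Xc.T @ Xc
    w, V = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w = w[order]
    V = V[:, order]
    return w, Xc @ V
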