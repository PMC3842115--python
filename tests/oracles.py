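"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — O(n^3) agglomeration, explicit
covariance eigendecomposition, exhaustive subset/permutation enumeration —
and shares no code with the package paths it checks.
"""

from itertools import combinations
from math import comb

import numpy as np


def brute_force_cophenetic(d: np.ndarray, method: str) -> np.ndarray:
    """Naive agglomeration: recompute all inter-cluster linkages each step.

    Returns the cophenetic distance matrix (merge height joining each leaf
    pair), which characterizes the dendrogram heights completely.
    """
    n = d.shape[0]
    clusters = [[i] for i in range(n)]
    coph = np.zeros((n, n))

    def linkage_dist(a, b):
        vals = [d[i, j] for i in a for j in b]
        if method == "complete":
            return max(vals)
        if method == "single":
            return min(vals)
        if method == "average":
            return sum(vals) / len(vals)
        raise ValueError(method)

    while len(clusters) > 1:
        best = None
        for ia in range(len(clusters)):
            for ib in range(ia + 1, len(clusters)):
                h = linkage_dist(clusters[ia], clusters[ib])
                if best is None or h < best[0]:
                    best = (h, ia, ib)
        h, ia, ib = best
        for i in clusters[ia]:
            for j in clusters[ib]:
                coph[i, j] = coph[j, i] = h
        clusters[ia] = clusters[ia] + clusters[ib]
        del clusters[ib]
    return coph


def eig_pca(x: np.ndarray):
    """PCA by explicit eigendecomposition of the column covariance matrix.

    Returns (|scores|, variance fractions) with components ordered by
    decreasing eigenvalue; score signs are dropped because they are arbitrary.
    """
    xc = x - x.mean(axis=0)
    cov = xc.T @ xc
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    n_comp = min(x.shape[0] - 1, x.shape[1])
    scores = xc @ evecs[:, :n_comp]
    frac = evals[:n_comp] / evals.sum()
    return np.abs(scores), frac


def enumerate_hypergeom_tail(universe: list, term_members: set, foreground: set) -> float:
    """P(overlap >= observed) by enumerating every |foreground|-subset of the
    universe.  Only feasible for small universes."""
    n = len(foreground)
    k_obs = len(foreground & term_members)
    hits = total = 0
    for subset in combinations(universe, n):
        total += 1
        if len(set(subset) & term_members) >= k_obs:
            hits += 1
    return hits / total


def enumerate_abs_ranksum_tail(values_in: np.ndarray, values_out: np.ndarray) -> float:
    """Exact one-sided p for the rank-sum of |values_in| being as large as
    observed, enumerating all assignments of group labels to the pooled
    absolute values (assumes no ties)."""
    pooled = np.abs(np.concatenate([values_in, values_out]))
    ranks = pooled.argsort().argsort() + 1  # 1-based ranks, no ties assumed
    n1 = len(values_in)
    observed = ranks[:n1].sum()
    hits = total = 0
    for positions in combinations(range(len(pooled)), n1):
        total += 1
        if ranks[list(positions)].sum() >= observed:
            hits += 1
    return hits / total
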