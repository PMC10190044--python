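"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: Tanimoto via
Python set arithmetic, local alignment via a quadratic Gotoh dynamic
programme, and walk transition probabilities via direct enumeration of
the bias rule.
"""

from __future__ import annotations

import numpy as np


def tanimoto_bitset(on_a: set[int], on_b: set[int]) -> float:
    """c / (|a| + |b| - c) over explicit bit sets."""
    c = len(on_a & on_b)
    denom = len(on_a) + len(on_b) - c
    if denom == 0:
        return 1.0
    return c / denom


def smith_waterman_affine(
    a: str, b: str, score_fn, gap_open: float, gap_extend: float
) -> float:
    """Best local alignment score with affine gaps (Gotoh DP), floor 0.

    A gap of length L costs gap_open + gap_extend * (L - 1).
    """
    n, m = len(a), len(b)
    neg = -1e9
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), neg)  # gap in a (consume b)
    F = np.full((n + 1, m + 1), neg)  # gap in b (consume a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            H[i][j] = max(
                0.0,
                H[i - 1][j - 1] + score_fn(a[i - 1], b[j - 1]),
                E[i][j],
                F[i][j],
            )
            best = max(best, H[i][j])
    return best


def normalized_local_similarity(
    a: str, b: str, score_fn, gap_open: float = 10.0, gap_extend: float = 0.5
) -> float:
    """Geometric-mean self-score normalisation of the SW score, clipped to [0, 1]."""
    s_ab = smith_waterman_affine(a, b, score_fn, gap_open, gap_extend)
    s_aa = smith_waterman_affine(a, a, score_fn, gap_open, gap_extend)
    s_bb = smith_waterman_affine(b, b, score_fn, gap_open, gap_extend)
    if s_aa <= 0 or s_bb <= 0:
        return 0.0
    return float(np.clip(s_ab / np.sqrt(s_aa * s_bb), 0.0, 1.0))


def blosum62_score_fn():
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    return lambda x, y: float(mat[x, y])


def enumerate_transition(g, prev, cur, p: float, q: float):
    """Second-order transition distribution by direct rule application."""
    nbrs = sorted(g.neighbors(cur))
    if not nbrs:
        return [], np.array([])
    weights = []
    for x in nbrs:
        w = g[cur][x].get("weight", 1.0)
        if prev is None:
            bias = 1.0
        elif x == prev:
            bias = 1.0 / p
        elif g.has_edge(x, prev):
            bias = 1.0
        else:
            bias = 1.0 / q
        weights.append(w * bias)
    weights = np.asarray(weights, dtype=float)
    return nbrs, weights / weights.sum()
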