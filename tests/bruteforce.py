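"""Independent brute-force oracles for the test suite.

Exhaustive enumeration of all pseudoknot-free structures (minimum hairpin
loop 3) for short sequences, scored by summing pair weights — deliberately
independent of the package's dynamic program and traceback.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

COMPLEMENT_SCORES = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "U"): 2, ("U", "A"): 2,
    ("G", "U"): 1, ("U", "G"): 1,
}


def enumerate_structures(n: int, can_pair, min_loop: int = 3):
    """All nested pair sets over positions 0..n-1 (yields tuples of 0-based
    (i, j) pairs).  ``can_pair(i, j)`` gates which pairs are allowed."""

    @lru_cache(maxsize=None)
    def rec(i, j):
        if j - i < min_loop + 1:
            return (((),) if j >= i else ((),))
        out = list(rec(i, j - 1))
        for k in range(i, j - min_loop):
            if can_pair(k, j):
                left = rec(i, k - 1) if k > i else ((),)
                right = rec(k + 1, j - 1)
                for a in left:
                    for b in right:
                        out.append(a + b + ((k, j),))
        return tuple(out)

    return rec(0, n - 1) if n > 0 else ((),)


def pair_weight(sequence, i, j, mode="unconstrained", rho=None,
                m=2.0, b=-0.6, hard_threshold=0.7):
    """Weight of pairing 0-based i, j, or None if the pair is disallowed.
    Mirrors the scoring contract, computed independently."""
    score = COMPLEMENT_SCORES.get((sequence[i], sequence[j]))
    if score is None:
        return None
    if mode == "hard":
        for p in (i, j):
            if rho is not None and not np.isnan(rho[p]) and rho[p] > hard_threshold:
                return None
    if mode == "soft":
        for p in (i, j):
            if rho is not None and not np.isnan(rho[p]):
                score -= m * np.log(rho[p] + 1) + b
    return score


def best_structure_score(sequence, mode="unconstrained", rho=None,
                         m=2.0, b=-0.6, hard_threshold=0.7, min_loop=3) -> float:
    """Maximum total weight over every valid nested structure, by exhaustive
    enumeration.  The empty structure (score 0) is always a candidate."""

    def can_pair(i, j):
        return pair_weight(sequence, i, j, mode, rho, m, b, hard_threshold) is not None

    best = 0.0
    for structure in enumerate_structures(len(sequence), can_pair, min_loop):
        total = sum(pair_weight(sequence, i, j, mode, rho, m, b, hard_threshold)
                    for i, j in structure)
        best = max(best, total)
    return best
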