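"""Reactivity-constrained nested secondary-structure prediction.

A Nussinov-style dynamic program maximizes a sum of base-pair weights
(GC 3, AU 2, GU 1) over all pseudoknot-free structures with a minimum
hairpin loop of 3.  Probing data enter either as Deigan-style soft
pseudo-energies, subtracting m*ln(rho+1)+b from the weight of any pair
touching a position with reactivity rho, or as hard constraints forbidding
pairs at positions above a reactivity threshold.  This trades the full
nearest-neighbor thermodynamic model for an exactly testable scorer that
preserves the constraint logic; a SHAPE-file exporter is provided for users
who want to drive an external thermodynamic folder instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import write_shape
from .types import ReactivityProfile, SecondaryStructure

_COMPLEMENT_SCORES = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "U"): 2, ("U", "A"): 2,
    ("G", "U"): 1, ("U", "G"): 1,
}


@dataclass
class FoldParams:
    """Folding knobs.

    ``slope_m``/``intercept_b`` are the SHAPE pseudo-energy parameters in
    pair-score units, scaled so that a fully reactive position (rho = 1)
    costs roughly one GU pair; ``hard_threshold`` is the reactivity above
    which hard mode forbids pairing.
    """

    min_loop: int = 3
    pair_scores: dict = field(default_factory=lambda: dict(_COMPLEMENT_SCORES))
    slope_m: float = 2.0
    intercept_b: float = -0.6
    hard_threshold: float = 0.7
    mode: str = "unconstrained"
    forbid_lonely_pairs: bool = False

    def __post_init__(self):
        if self.min_loop < 3:
            raise ValueError("min_loop must be >= 3")
        if not (0 < self.hard_threshold < 1):
            raise ValueError("hard_threshold must be in (0, 1)")
        if self.mode not in ("unconstrained", "soft", "hard"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if any(v <= 0 for v in self.pair_scores.values()):
            raise ValueError("pair scores must be positive")


def pseudo_energy(rho, m: float = 2.0, b: float = -0.6):
    """Deigan-form pairing penalty m*ln(rho+1)+b; missing (NaN) reactivity
    contributes no penalty.  Accepts scalars or arrays."""
    rho_arr = np.atleast_1d(np.asarray(rho, dtype=float))
    if (rho_arr[~np.isnan(rho_arr)] < 0).any():
        raise ValueError("reactivity must be >= 0")
    out = np.where(np.isnan(rho_arr), 0.0, m * np.log(rho_arr + 1) + b)
    return float(out[0]) if np.asarray(rho).ndim == 0 else out


def _reactivity_track(profile) -> np.ndarray | None:
    if profile is None:
        return None
    if isinstance(profile, ReactivityProfile):
        return profile.combined
    return np.asarray(profile, dtype=float)


def pair_weight_matrix(sequence: str, profile=None, params: FoldParams | None = None) -> np.ndarray:
    """Weight w[i, j] (0-based) of pairing i with j; NaN where disallowed.

    In soft mode w = pair_score - pe(rho_i) - pe(rho_j); hard mode forbids
    pairs at positions above the threshold; N never pairs.
    """
    params = params or FoldParams()
    n = len(sequence)
    rho = _reactivity_track(profile)
    if params.mode in ("soft", "hard"):
        if rho is None:
            raise ValueError(f"{params.mode} mode requires a reactivity profile")
        if rho.size != n:
            raise ValueError("profile length does not match sequence")
    w = np.full((n, n), np.nan)
    pe = None
    if params.mode == "soft":
        pe = pseudo_energy(rho, params.slope_m, params.intercept_b)
    forbidden = None
    if params.mode == "hard":
        forbidden = ~np.isnan(rho) & (rho > params.hard_threshold)
    for i in range(n):
        for j in range(i + params.min_loop + 1, n):
            score = params.pair_scores.get((sequence[i], sequence[j]))
            if score is None:
                continue
            if forbidden is not None and (forbidden[i] or forbidden[j]):
                continue
            if pe is not None:
                score = score - pe[i] - pe[j]
            w[i, j] = score
    return w


def score_structure(structure: SecondaryStructure, sequence: str, profile=None,
                    params: FoldParams | None = None) -> float:
    """Total pair weight of a structure under the given scoring mode."""
    w = pair_weight_matrix(sequence, profile, params)
    total = 0.0
    for i, j in structure.pairs:
        v = w[i - 1, j - 1]
        if np.isnan(v):
            raise ValueError(f"pair ({i}, {j}) not allowed under current parameters")
        total += v
    return total


def fold(sequence: str, profile=None, params: FoldParams | None = None,
         transcript_id: str = "", return_score: bool = False):
    """Predict the maximum-weight nested structure for a sequence.

    Pairs with non-positive net weight are never taken, so constraints can
    only remove pairs.  Traceback is deterministic: at ties the pair branch
    wins, then leaving i unpaired, then leaving j unpaired, then the smallest
    bifurcation point.
    """
    if not sequence:
        raise ValueError("empty sequence")
    params = params or FoldParams()
    n = len(sequence)
    w = pair_weight_matrix(sequence, profile, params)
    allow = ~np.isnan(w) & (w > 0)
    wv = np.where(allow, w, 0.0)

    S = np.zeros((n + 1, n + 1))  # S[i, j], 0-based inclusive; j < i is empty
    for span in range(params.min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = (S[i, i:j] + S[i + 1:j + 1, j]).max()
            if allow[i, j]:
                cand = S[i + 1, j - 1] + wv[i, j]
                if cand > best:
                    best = cand
            S[i, j] = best

    pairs = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= params.min_loop:
            continue
        if allow[i, j] and S[i, j] == S[i + 1, j - 1] + wv[i, j]:
            pairs.append((i + 1, j + 1))
            stack.append((i + 1, j - 1))
        elif S[i, j] == S[i + 1, j]:
            stack.append((i + 1, j))
        elif S[i, j] == S[i, j - 1]:
            stack.append((i, j - 1))
        else:
            for k in range(i + 1, j - 1):
                if S[i, j] == S[i, k] + S[k + 1, j]:
                    stack.append((i, k))
                    stack.append((k + 1, j))
                    break
            else:  # pragma: no cover - DP/traceback consistency guard
                raise RuntimeError("traceback failed to reproduce DP score")

    if params.forbid_lonely_pairs:
        pairset = set(pairs)
        pairs = [(i, j) for (i, j) in pairs
                 if (i + 1, j - 1) in pairset or (i - 1, j + 1) in pairset]
    structure = SecondaryStructure(transcript_id=transcript_id, pairs=frozenset(pairs), length=n)
    if return_score:
        return structure, float(S[0, n - 1])
    return structure


def fold_with_shape_export(sequence: str, profile, path, params: FoldParams | None = None,
                           transcript_id: str = "") -> SecondaryStructure:
    """Write the profile as a SHAPE file (for external thermodynamic folders)
    and return the internal fold."""
    if not sequence:
        raise ValueError("empty sequence")
    rho = _reactivity_track(profile)
    write_shape(rho, path)
    return fold(sequence, profile, params, transcript_id=transcript_id)
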