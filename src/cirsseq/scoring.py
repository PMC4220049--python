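"""Structure comparison and reactive-site accounting.

PPV is the fraction of predicted base pairs present in the reference
structure; sensitivity the fraction of reference pairs recovered.  The
reactive-site accounting partitions highly reactive residues into true
positives (single-stranded) and false positives (double-stranded), with a
relaxed accounting that also accepts helix-terminal pairs — the outermost or
innermost pair of a stack, or a paired base flanking a bulge or loop — which
are structurally flexible and chemically accessible despite being paired.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import SecondaryStructure


@dataclass
class ScoreReport:
    """PPV/sensitivity of a predicted structure against a reference.

    Undefined ratios (zero predicted or reference pairs) are None, never 0 or 1.
    """

    ppv: float | None
    sensitivity: float | None
    n_predicted_pairs: int
    n_true_pairs: int
    n_common: int


def ppv_sensitivity(predicted: SecondaryStructure, reference: SecondaryStructure,
                    slip: int = 0) -> ScoreReport:
    """Score predicted against reference pairs.

    With slip=0 a predicted pair must match a reference pair exactly; with
    slip=1, (i, j) may match (i, j), (i±1, j) or (i, j±1), each reference
    pair consumable once (a maximum bipartite matching).
    """
    if predicted.length != reference.length:
        raise ValueError("structures cover different lengths")
    if slip not in (0, 1):
        raise ValueError("slip must be 0 or 1")
    pred = sorted(predicted.pairs)
    ref = sorted(reference.pairs)
    if slip == 0:
        n_common = len(predicted.pairs & reference.pairs)
    else:
        n_common = _max_slip_matching(pred, ref)
    ppv = n_common / len(pred) if pred else None
    sens = n_common / len(ref) if ref else None
    return ScoreReport(ppv=ppv, sensitivity=sens, n_predicted_pairs=len(pred),
                       n_true_pairs=len(ref), n_common=n_common)


def _max_slip_matching(pred: list, ref: list) -> int:
    """Maximum matching between predicted and reference pairs under the
    one-coordinate slip rule."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import maximum_bipartite_matching

    if not pred or not ref:
        return 0
    ref_index = {p: k for k, p in enumerate(ref)}
    rows, cols = [], []
    for a, (i, j) in enumerate(pred):
        for cand in ((i, j), (i - 1, j), (i + 1, j), (i, j - 1), (i, j + 1)):
            k = ref_index.get(cand)
            if k is not None:
                rows.append(a)
                cols.append(k)
    if not rows:
        return 0
    graph = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(len(pred), len(ref)))
    match = maximum_bipartite_matching(graph, perm_type="column")
    return int((match >= 0).sum())


def annotate_helix_context(structure: SecondaryStructure) -> list[str]:
    """Per-position label: unpaired, helix_internal, or helix_terminal.

    Helices are maximal runs of stacked pairs (i, j), (i+1, j-1), ...  A
    paired position is helix_terminal if its pair opens or closes its helix,
    or if an immediate sequence neighbor is unpaired (adjacent to a bulge or
    loop); otherwise helix_internal.
    """
    n = structure.length
    labels = ["unpaired"] * n
    pairset = set(structure.pairs)
    paired = np.zeros(n + 2, dtype=bool)  # 1-based with sentinels
    for i, j in pairset:
        paired[i] = paired[j] = True

    for i, j in sorted(pairset):
        if (i - 1, j + 1) in pairset:
            continue  # continuation of a helix already walked
        helix = [(i, j)]
        while (helix[-1][0] + 1, helix[-1][1] - 1) in pairset:
            helix.append((helix[-1][0] + 1, helix[-1][1] - 1))
        for idx, (a, b) in enumerate(helix):
            terminal_pair = idx == 0 or idx == len(helix) - 1
            for p in (a, b):
                neighbor_unpaired = (p > 1 and not paired[p - 1]) or (p < n and not paired[p + 1])
                labels[p - 1] = "helix_terminal" if (terminal_pair or neighbor_unpaired) else "helix_internal"
    return labels


@dataclass
class ReactiveSiteAccounting:
    """Accounting of highly reactive residues against a known structure.

    Strict true positives are unpaired; the relaxed accounting also accepts
    helix-terminal positions.  Percentages are over all highly reactive
    positions, None when no position exceeds the threshold.
    """

    n_high: int
    tp_strict: int
    fp_strict: int
    tp_relaxed: int
    fp_relaxed: int

    def _pct(self, k: int) -> float | None:
        return None if self.n_high == 0 else 100.0 * k / self.n_high

    @property
    def tp_strict_pct(self):
        return self._pct(self.tp_strict)

    @property
    def fp_strict_pct(self):
        return self._pct(self.fp_strict)

    @property
    def tp_relaxed_pct(self):
        return self._pct(self.tp_relaxed)

    @property
    def fp_relaxed_pct(self):
        return self._pct(self.fp_relaxed)


def reactive_site_accounting(structure: SecondaryStructure, combined: np.ndarray,
                             threshold: float = 0.7) -> ReactiveSiteAccounting:
    """Partition highly reactive positions (combined > threshold) by their
    structural context."""
    combined = np.asarray(combined, dtype=float)
    if combined.size != structure.length:
        raise ValueError("profile and structure lengths differ")
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    labels = annotate_helix_context(structure)
    high = np.flatnonzero(~np.isnan(combined) & (combined > threshold))
    tp_strict = sum(1 for k in high if labels[k] == "unpaired")
    tp_relaxed = sum(1 for k in high if labels[k] in ("unpaired", "helix_terminal"))
    n = high.size
    return ReactiveSiteAccounting(
        n_high=n,
        tp_strict=tp_strict, fp_strict=n - tp_strict,
        tp_relaxed=tp_relaxed, fp_relaxed=n - tp_relaxed,
    )
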