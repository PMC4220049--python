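"""PPV/sensitivity scoring, helix context, reactive-site accounting."""

import itertools

import numpy as np
import pytest

from cirsseq.io import dotbracket_to_pairs
from cirsseq.scoring import annotate_helix_context, ppv_sensitivity, reactive_site_accounting
from cirsseq.simulate import SimParams, make_structured_transcript
from cirsseq.types import SecondaryStructure


def _ss(pairs, length=20):
    return SecondaryStructure("t", frozenset(pairs), length)


def _bruteforce_slip_common(pred, ref):
    """Max one-to-one correspondence under the slip rule, by enumerating all
    injective assignments (small inputs only)."""
    pred, ref = list(pred), list(ref)

    def compatible(p, r):
        (i, j), (k, l) = p, r
        return (i, j) == (k, l) or (abs(i - k) == 1 and j == l) or (i == k and abs(j - l) == 1)

    best = 0
    for m in range(min(len(pred), len(ref)), 0, -1):
        for pred_sub in itertools.combinations(pred, m):
            for ref_perm in itertools.permutations(ref, m):
                if all(compatible(p, r) for p, r in zip(pred_sub, ref_perm)):
                    return m
    return best


class TestPpvSensitivity:
    def test_identical_structures_score_one(self):
        s = _ss({(1, 10), (2, 9), (3, 8), (4, 7)})
        rep = ppv_sensitivity(s, s)
        assert rep.ppv == 1.0 and rep.sensitivity == 1.0 and rep.n_common == 4

    def test_partial_overlap_by_hand(self):
        pred = _ss({(1, 10), (2, 9), (3, 8)})
        ref = _ss({(2, 9), (3, 8), (4, 7), (5, 6)})
        rep = ppv_sensitivity(pred, ref)
        assert rep.ppv == pytest.approx(2 / 3)
        assert rep.sensitivity == pytest.approx(0.5)

    def test_slip_accepts_one_coordinate_shift(self):
        rep = ppv_sensitivity(_ss({(2, 9)}), _ss({(1, 9)}), slip=1)
        assert rep.ppv == 1.0

    def test_zero_pairs_reported_as_missing(self):
        empty = _ss(set())
        full = _ss({(1, 10)})
        rep = ppv_sensitivity(empty, full)
        assert rep.ppv is None and rep.sensitivity == 0.0
        rep = ppv_sensitivity(full, empty)
        assert rep.sensitivity is None and rep.ppv == 0.0

    def test_self_score_is_one_on_generated_structures(self):
        params = SimParams()
        for seed in range(5):
            _, ss = make_structured_transcript(params, seed)
            rep = ppv_sensitivity(ss, ss)
            assert rep.ppv == 1.0 and rep.sensitivity == 1.0

    def test_slip_never_below_exact(self, rng):
        params = SimParams()
        for seed in range(10):
            _, a = make_structured_transcript(params, seed)
            _, b = make_structured_transcript(params, seed + 100, length=a.length)
            r0 = ppv_sensitivity(a, b, slip=0)
            r1 = ppv_sensitivity(a, b, slip=1)
            assert r1.n_common >= r0.n_common

    def test_slip_matching_agrees_with_bruteforce(self, rng):
        for _ in range(30):
            n = 30
            pairs_a, pairs_b = [], []
            for target in (pairs_a, pairs_b):
                used = set()
                for _ in range(int(rng.integers(1, 6))):
                    i = int(rng.integers(1, n - 5))
                    j = int(rng.integers(i + 4, n + 1))
                    if not ({i, j} & used):
                        target.append((i, j))
                        used |= {i, j}
            try:
                a, b = _ss(pairs_a, n), _ss(pairs_b, n)
            except ValueError:  # crossing pairs: not a valid nested fixture
                continue
            rep = ppv_sensitivity(a, b, slip=1)
            assert rep.n_common == _bruteforce_slip_common(a.pairs, b.pairs)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ppv_sensitivity(_ss(set(), 10), _ss(set(), 12))


class TestHelixContext:
    def test_single_helix_decomposition(self):
        labels = annotate_helix_context(dotbracket_to_pairs("((((....))))"))
        expect = {1: "helix_terminal", 4: "helix_terminal", 9: "helix_terminal", 12: "helix_terminal",
                  2: "helix_internal", 3: "helix_internal", 10: "helix_internal", 11: "helix_internal"}
        for pos, lab in expect.items():
            assert labels[pos - 1] == lab
        assert all(labels[k] == "unpaired" for k in range(4, 8))

    def test_isolated_pair_is_terminal(self):
        labels = annotate_helix_context(_ss({(2, 9)}, 10))
        assert labels[1] == "helix_terminal" and labels[8] == "helix_terminal"

    def test_fully_unpaired(self):
        assert set(annotate_helix_context(_ss(set(), 8))) == {"unpaired"}

    def test_bulge_neighbor_is_terminal(self):
        # (((.(((...))))))  : pair (3,14) flanks the bulge at 4
        labels = annotate_helix_context(dotbracket_to_pairs("(((.(((...))))))"))
        assert labels[2] == "helix_terminal"
        assert labels[1] == "helix_internal"


class TestReactiveSiteAccounting:
    def test_all_high_unpaired_is_perfect(self):
        ss = dotbracket_to_pairs("((((....))))")
        combined = np.zeros(12)
        combined[4:8] = 0.9  # loop positions
        acc = reactive_site_accounting(ss, combined)
        assert acc.tp_strict_pct == 100.0 and acc.fp_strict_pct == 0.0

    def test_helix_terminal_rescued_by_relaxed_accounting(self):
        ss = dotbracket_to_pairs("((((....))))")
        combined = np.zeros(12)
        combined[3] = 0.9  # position 4: helix-terminal pair
        combined[5] = 0.9  # position 6: unpaired
        acc = reactive_site_accounting(ss, combined)
        assert acc.tp_strict_pct == pytest.approx(50.0)
        assert acc.tp_relaxed_pct == pytest.approx(100.0)

    def test_internal_pair_is_false_positive_everywhere(self):
        ss = dotbracket_to_pairs("((((....))))")
        combined = np.zeros(12)
        combined[1] = 0.9  # position 2: helix-internal
        acc = reactive_site_accounting(ss, combined)
        assert acc.fp_strict_pct == 100.0 and acc.fp_relaxed_pct == 100.0

    def test_no_high_positions_flagged_not_zero_or_one(self):
        ss = dotbracket_to_pairs("((((....))))")
        acc = reactive_site_accounting(ss, np.zeros(12))
        assert acc.n_high == 0 and acc.tp_strict_pct is None

    def test_coherence_on_random_fixtures(self, rng):
        params = SimParams()
        for seed in range(15):
            _, ss = make_structured_transcript(params, seed)
            combined = rng.uniform(0, 1, ss.length)
            acc = reactive_site_accounting(ss, combined)
            if acc.n_high == 0:
                continue
            assert acc.tp_relaxed_pct >= acc.tp_strict_pct
            assert acc.tp_strict_pct + acc.fp_strict_pct == pytest.approx(100.0)
            assert acc.tp_relaxed_pct + acc.fp_relaxed_pct == pytest.approx(100.0)
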