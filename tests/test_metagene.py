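"""Meta-gene aggregation, region statistics, periodicity, biotype contrast."""

import numpy as np
import pytest

from cirsseq.metagene import (
    base_normalized_average,
    biotype_comparison,
    codon_periodicity,
    metagene_profile,
    region_averages,
    wilcoxon_ranksum,
)
from cirsseq.types import ReactivityProfile, TranscriptRecord


def _profile(tid, combined):
    combined = np.asarray(combined, dtype=float)
    nan = np.full(combined.size, np.nan)
    return ReactivityProfile(tid, nan, nan, nan, nan, combined, np.isnan(combined))


def _mrna(tid, length=400, cds_start=101, cds_end=310, sequence=None):
    seq = sequence or ("ACGU" * (length // 4 + 1))[:length]
    return TranscriptRecord(tid, seq, cds_start=cds_start, cds_end=cds_end, biotype="mRNA")


class TestWilcoxon:
    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(5)
        p = wilcoxon_ranksum(rng.normal(size=500), rng.normal(size=500))
        assert p > 0.001

    def test_shifted_distributions_detected(self):
        rng = np.random.default_rng(5)
        p = wilcoxon_ranksum(rng.normal(0.5, 1, 500), rng.normal(0, 1, 500))
        assert p < 1e-6

    def test_small_samples_use_exact_enumeration(self):
        p = wilcoxon_ranksum([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert p == pytest.approx(0.1, abs=0.01)  # 2/20 orderings


class TestMetageneProfile:
    def test_constant_profiles_give_flat_track(self):
        transcripts = [_mrna(f"t{k}") for k in range(3)]
        profiles = [_profile(t.id, np.full(400, 0.5)) for t in transcripts]
        df = metagene_profile(profiles, transcripts)
        assert np.allclose(df["mean"], 0.5)
        assert (df["n"] == 3).all()
        assert len(df) == 300  # 50 + 100 + 100 + 50 offsets

    def test_single_transcript_recovers_own_values(self):
        t = _mrna("t0")
        vals = np.linspace(0, 1, 400)
        df = metagene_profile([_profile("t0", vals)], [t])
        first_cds = df[(df.segment == "cds_first") & (df.offset == 0)]["mean"].item()
        assert first_cds == pytest.approx(vals[t.cds_start - 1])
        last_utr5 = df[(df.segment == "utr5_last") & (df.offset == -1)]["mean"].item()
        assert last_utr5 == pytest.approx(vals[t.cds_start - 2])

    def test_short_segments_contribute_available_offsets_only(self):
        t = TranscriptRecord("t", "A" * 120, cds_start=21, cds_end=110, biotype="mRNA")  # CDS 90 nt
        df = metagene_profile([_profile("t", np.full(120, 0.3))], [t])
        utr5 = df[df.segment == "utr5_last"]
        assert utr5[utr5.offset < -20]["n"].sum() == 0
        assert (utr5[utr5.offset >= -20]["n"] == 1).all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            metagene_profile([], [])


class TestRegionAverages:
    def test_planted_shift_detected_with_correct_sign(self):
        rng = np.random.default_rng(77)
        transcripts, profiles = [], []
        for k in range(100):
            t = _mrna(f"t{k}")
            vals = rng.uniform(0.1, 0.6, 400)
            vals[: t.cds_start - 1] -= 0.05  # depress the 5' UTR
            vals = np.clip(vals, 0, 1)
            transcripts.append(t)
            profiles.append(_profile(t.id, vals))
        df = region_averages(profiles, transcripts).set_index("region")
        assert df.loc["utr5", "mean"] < df.loc["cds", "mean"]
        assert df.loc["utr5", "p_vs_cds"] < 1e-6

    def test_null_regions_have_similar_means(self):
        rng = np.random.default_rng(78)
        transcripts = [_mrna(f"t{k}") for k in range(50)]
        profiles = [_profile(t.id, rng.uniform(0, 1, 400)) for t in transcripts]
        df = region_averages(profiles, transcripts).set_index("region")
        assert abs(df.loc["utr5", "mean"] - df.loc["cds", "mean"]) < 0.02
        assert df.loc["utr5", "p_vs_cds"] > 1e-4

    def test_kozak_window_truncated_at_transcript_start(self):
        t = TranscriptRecord("t", "A" * 60, cds_start=4, cds_end=48, biotype="mRNA")
        df = region_averages([_profile("t", np.full(60, 0.2))], [t]).set_index("region")
        assert df.loc["kozak", "n_positions"] == 5  # positions 1..5

    def test_stop_codon_window_is_six_positions(self):
        t = _mrna("t")
        vals = np.full(400, 0.1)
        vals[t.cds_end - 6: t.cds_end] = 0.9  # 1-based cds_end-5..cds_end
        df = region_averages([_profile("t", vals)], [t]).set_index("region")
        assert df.loc["stop_codon", "n_positions"] == 6
        assert df.loc["stop_codon", "mean"] == pytest.approx(0.9)


class TestCodonPeriodicity:
    def test_constant_profile_gives_equal_frames(self):
        transcripts = [_mrna(f"t{k}") for k in range(3)]
        profiles = [_profile(t.id, np.full(400, 0.4)) for t in transcripts]
        res = codon_periodicity(profiles, transcripts)
        cds = res.frame_means[res.frame_means.segment == "cds_first"]
        assert np.allclose(cds["mean"], 0.4)

    def test_frame_assignment_arithmetic(self):
        t = TranscriptRecord("t", "A" * 200, cds_start=10, cds_end=129, biotype="mRNA")
        vals = np.zeros(200)
        # frame 1 positions from cds_start: 10, 13, 16, ...
        pos = np.arange(10, 130, 3)
        vals[pos - 1] = 0.9
        res = codon_periodicity([_profile("t", vals)], [t])
        means = res.frame_means.set_index(["segment", "frame"])["mean"]
        assert means[("cds_first", 1)] == pytest.approx(0.9)
        assert means[("cds_first", 2)] == pytest.approx(0.0)
        assert means[("cds_first", 3)] == pytest.approx(0.0)

    def test_planted_frame_boost_confined_to_cds(self):
        rng = np.random.default_rng(9)
        transcripts, profiles = [], []
        for k in range(100):
            t = _mrna(f"t{k}")
            vals = rng.uniform(0.2, 0.4, 400)
            frame1 = np.arange(t.cds_start, t.cds_end + 1, 3)
            vals[frame1 - 1] += 0.05
            transcripts.append(t)
            profiles.append(_profile(t.id, np.clip(vals, 0, 1)))
        res = codon_periodicity(profiles, transcripts)
        means = res.frame_means.set_index(["segment", "frame"])["mean"]
        assert means[("cds_first", 1)] > means[("cds_first", 2)]
        assert means[("cds_first", 1)] > means[("cds_first", 3)]
        utr = res.frame_means[res.frame_means.segment == "utr5_last"]["mean"]
        assert utr.max() - utr.min() < 0.02
        tests = res.tests.set_index(["segment", "frame_a", "frame_b"])["p"]
        assert tests[("cds_first", 1, 2)] < 1e-6

    def test_span_must_be_multiple_of_three(self):
        with pytest.raises(ValueError, match="divisible"):
            codon_periodicity([_profile("t", np.zeros(10))], [_mrna("t")], span=100)


class TestBiotypeComparison:
    def test_base_normalized_average_is_composition_invariant(self):
        # reactivity 0.2 on A/C, 0.4 on G/U -> 0.3 regardless of composition
        for seq in ("AAACGU", "ACGUUUUUU", "AGGGGG"):
            vals = np.array([0.2 if b in "AC" else 0.4 for b in seq])
            value, complete = base_normalized_average(_profile("t", vals), seq)
            assert value == pytest.approx(0.3)

    def test_incomplete_base_representation_flagged(self):
        value, complete = base_normalized_average(_profile("t", np.full(6, 0.5)), "AAACCC")
        assert not complete and value == pytest.approx(0.5)

    def test_null_groups_not_significant(self):
        rng = np.random.default_rng(31)
        transcripts, profiles = [], []
        for k in range(100):
            biotype = "mRNA" if k < 50 else "lincRNA"
            seq = "".join(rng.choice(list("ACGU"), 80))
            transcripts.append(TranscriptRecord(f"t{k}", seq, biotype=biotype))
            profiles.append(_profile(f"t{k}", rng.uniform(0, 1, 80)))
        _, tests = biotype_comparison(profiles, transcripts)
        assert tests.iloc[0]["p_vs_mrna"] > 0.01

    def test_planted_biotype_shift_detected(self):
        rng = np.random.default_rng(32)
        transcripts, profiles = [], []
        for k in range(200):
            biotype = "mRNA" if k < 100 else "snoRNA"
            shift = 0.0 if biotype == "mRNA" else -0.05
            seq = "".join(rng.choice(list("ACGU"), 80))
            transcripts.append(TranscriptRecord(f"t{k}", seq, biotype=biotype))
            profiles.append(_profile(f"t{k}", np.clip(rng.uniform(0.2, 0.6, 80) + shift, 0, 1)))
        _, tests = biotype_comparison(profiles, transcripts)
        row = tests.set_index("biotype").loc["snoRNA"]
        assert row["delta_mean"] < 0
        assert row["p_vs_mrna"] < 1e-4
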