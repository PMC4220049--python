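"""Transcriptome-level aggregation of combined reactivity.

Meta-gene profiles align transcripts on the start and stop codons and average
reactivity per anchor-relative offset; region statistics pool position-level
values (5' UTR, Kozak window, CDS, stop-codon window, 3' UTR) and compare
them with the Wilcoxon rank-sum test; codon periodicity averages reactivity
by reading-frame position; the biotype comparison contrasts base-normalized
per-transcript average reactivities between RNA classes.

Position-level pooling (rather than per-transcript means) is used for the
region and frame statistics: at transcriptome scale each position is one
observation, which is what gives these comparisons their power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import ReactivityProfile, TranscriptRecord

DEFAULT_WINDOWS = {"utr5_last": 50, "cds_first": 100, "cds_last": 100, "utr3_first": 50}


def wilcoxon_ranksum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value: exact enumeration
    for small tie-free samples, normal approximation with tie correction
    otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        return float("nan")
    small = min(x.size, y.size) <= 20
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (small and not ties) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def _values(profile: ReactivityProfile, positions: np.ndarray) -> np.ndarray:
    """Unmasked combined values at 1-based positions (silently clipped to the
    transcript)."""
    positions = positions[(positions >= 1) & (positions <= profile.length)]
    v = profile.combined[positions - 1]
    return v[~np.isnan(v)]


def _by_id(profiles) -> dict[str, ReactivityProfile]:
    return {p.transcript_id: p for p in profiles}


def metagene_profile(profiles, transcripts, windows=None) -> pd.DataFrame:
    """Anchor-aligned mean reactivity per offset across mRNAs.

    Segments: the last ``utr5_last`` nt of the 5' UTR and first ``cds_first``
    of the CDS (offsets relative to the start codon: position = cds_start +
    offset), and the last ``cds_last`` nt of the CDS and first ``utr3_first``
    of the 3' UTR (position = cds_end + offset).  Transcripts with a segment
    shorter than its window contribute only their available offsets.

    Returns a tidy frame: segment, offset, mean, n.
    """
    windows = windows or DEFAULT_WINDOWS
    prof = _by_id(profiles)
    annotated = [t for t in transcripts if t.has_cds and t.id in prof]
    if not annotated:
        raise ValueError("no CDS-annotated transcripts with profiles")

    segments = {
        "utr5_last": np.arange(-windows["utr5_last"], 0),
        "cds_first": np.arange(0, windows["cds_first"]),
        "cds_last": np.arange(-windows["cds_last"] + 1, 1),
        "utr3_first": np.arange(1, windows["utr3_first"] + 1),
    }
    rows = []
    for segment, offsets in segments.items():
        sums = np.zeros(offsets.size)
        ns = np.zeros(offsets.size, dtype=int)
        for t in annotated:
            p = prof[t.id]
            anchor = t.cds_start if segment in ("utr5_last", "cds_first") else t.cds_end
            pos = anchor + offsets
            if segment == "utr5_last":
                valid = pos >= 1
            elif segment == "cds_first":
                valid = pos <= t.cds_end
            elif segment == "cds_last":
                valid = pos >= t.cds_start
            else:
                valid = pos <= t.length
            pos_v = np.where(valid, np.clip(pos, 1, p.length), 1)
            vals = p.combined[pos_v - 1]
            ok = valid & (pos <= p.length) & (pos >= 1) & ~np.isnan(vals)
            sums[ok] += vals[ok]
            ns[ok] += 1
        mean = np.where(ns > 0, sums / np.maximum(ns, 1), np.nan)
        for off, m, k in zip(offsets, mean, ns):
            rows.append({"segment": segment, "offset": int(off), "mean": m, "n": int(k)})
    return pd.DataFrame(rows)


def region_averages(profiles, transcripts, utr_window: int = 50) -> pd.DataFrame:
    """Pooled position-level reactivity means per region, with Wilcoxon
    rank-sum p-values against the CDS region.

    Regions (1-based, relative to the CDS): 5' UTR = the ``utr_window`` nt
    immediately preceding the Kozak window; Kozak = cds_start-6 .. cds_start+1;
    CDS = first and last 100 nt of the coding region; stop codon window =
    cds_end-5 .. cds_end (the stop codon plus 3 nt upstream); 3' UTR = first
    ``utr_window`` nt after cds_end.  Windows are truncated at transcript ends.
    """
    prof = _by_id(profiles)
    annotated = [t for t in transcripts if t.has_cds and t.id in prof]
    if not annotated:
        raise ValueError("no CDS-annotated transcripts with profiles")

    pooled: dict[str, list] = {r: [] for r in ("utr5", "kozak", "cds", "stop_codon", "utr3")}
    for t in annotated:
        p = prof[t.id]
        cs, ce = t.cds_start, t.cds_end
        cds_pos = np.unique(np.concatenate([
            np.arange(cs, min(cs + 100, ce + 1)),
            np.arange(max(ce - 99, cs), ce + 1),
        ]))
        windows = {
            "utr5": np.arange(max(1, cs - 6 - utr_window), cs - 6),
            "kozak": np.arange(max(1, cs - 6), cs + 2),
            "cds": cds_pos,
            "stop_codon": np.arange(ce - 5, ce + 1),
            "utr3": np.arange(ce + 1, min(t.length, ce + utr_window) + 1),
        }
        for region, pos in windows.items():
            pooled[region].append(_values(p, pos))

    pooled = {r: np.concatenate(v) if v else np.array([]) for r, v in pooled.items()}
    rows = []
    for region, vals in pooled.items():
        p_vs_cds = np.nan if region == "cds" else wilcoxon_ranksum(vals, pooled["cds"])
        rows.append({
            "region": region,
            "mean": float(np.mean(vals)) if vals.size else np.nan,
            "n_positions": int(vals.size),
            "p_vs_cds": p_vs_cds,
        })
    return pd.DataFrame(rows)


@dataclass
class CodonPeriodicityResult:
    frame_means: pd.DataFrame  # segment, frame, mean, n
    tests: pd.DataFrame        # segment, frame_a, frame_b, p


def codon_periodicity(profiles, transcripts, span: int = 99, utr_span: int = 48
                      ) -> CodonPeriodicityResult:
    """Mean reactivity per reading-frame position in the first and last
    ``span`` nt of the CDS, with UTR control segments phased from the
    UTR/CDS boundary (frame of position p is ((p - cds_start) mod 3) + 1 on
    the 5' side, ((p - cds_end - 1) mod 3) + 1 on the 3' side)."""
    if span % 3 != 0 or utr_span % 3 != 0:
        raise ValueError("spans must be divisible by 3")
    prof = _by_id(profiles)
    annotated = [t for t in transcripts if t.has_cds and t.id in prof]
    if not annotated:
        raise ValueError("no CDS-annotated transcripts with profiles")

    pooled: dict[tuple, list] = {}
    for t in annotated:
        p = prof[t.id]
        cs, ce = t.cds_start, t.cds_end
        cds_len = ce - cs + 1
        segs = {}
        if cds_len >= span:
            segs["cds_first"] = np.arange(cs, cs + span)
            segs["cds_last"] = np.arange(ce - span + 1, ce + 1)
        segs["utr5_last"] = np.arange(max(1, cs - utr_span), cs)
        segs["utr3_first"] = np.arange(ce + 1, min(t.length, ce + utr_span) + 1)
        for segment, pos in segs.items():
            anchor = cs if segment in ("cds_first", "cds_last", "utr5_last") else ce + 1
            frames = ((pos - anchor) % 3) + 1
            vals = p.combined[pos - 1]
            ok = ~np.isnan(vals)
            for f in (1, 2, 3):
                sel = ok & (frames == f)
                if sel.any():
                    pooled.setdefault((segment, f), []).append(vals[sel])

    pooled = {k: np.concatenate(v) for k, v in pooled.items()}
    mean_rows = [
        {"segment": s, "frame": f, "mean": float(np.mean(v)), "n": int(v.size)}
        for (s, f), v in sorted(pooled.items())
    ]
    test_rows = []
    for segment in sorted({s for s, _ in pooled}):
        for fa, fb in ((1, 2), (1, 3), (2, 3)):
            va = pooled.get((segment, fa))
            vb = pooled.get((segment, fb))
            if va is None or vb is None:
                continue
            test_rows.append({"segment": segment, "frame_a": fa, "frame_b": fb,
                              "p": wilcoxon_ranksum(va, vb)})
    return CodonPeriodicityResult(pd.DataFrame(mean_rows), pd.DataFrame(test_rows))


def base_normalized_average(profile: ReactivityProfile, sequence: str) -> tuple[float, bool]:
    """Per-transcript average reactivity normalized for base composition:
    the mean is taken within each base identity (A, C, G, U) over unmasked
    positions, then the available base means are averaged.

    Returns (value, complete) where complete is False when fewer than four
    bases are represented.
    """
    base = np.frombuffer(sequence.encode(), dtype=np.uint8)
    means = []
    for b in b"ACGU":
        sel = (base == b) & ~np.isnan(profile.combined)
        if sel.any():
            means.append(float(np.mean(profile.combined[sel])))
    if not means:
        return float("nan"), False
    return float(np.mean(means)), len(means) == 4


def biotype_comparison(profiles, transcripts) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Base-normalized average reactivity per transcript, grouped by biotype,
    with a Wilcoxon rank-sum test of each non-mRNA class against mRNA.

    Returns (per_transcript, tests): per_transcript has transcript_id,
    biotype, value, complete_bases; tests has biotype, n, n_mrna, delta_mean,
    p_vs_mrna.
    """
    prof = _by_id(profiles)
    rows = []
    for t in transcripts:
        if t.id not in prof:
            continue
        value, complete = base_normalized_average(prof[t.id], t.sequence)
        if not np.isnan(value):
            rows.append({"transcript_id": t.id, "biotype": t.biotype,
                         "value": value, "complete_bases": complete})
    per_transcript = pd.DataFrame(rows)
    if per_transcript.empty:
        raise ValueError("no transcripts with usable profiles")

    mrna = per_transcript.loc[per_transcript["biotype"] == "mRNA", "value"].to_numpy()
    test_rows = []
    for biotype, grp in per_transcript.groupby("biotype"):
        if biotype == "mRNA":
            continue
        vals = grp["value"].to_numpy()
        test_rows.append({
            "biotype": biotype, "n": vals.size, "n_mrna": mrna.size,
            "delta_mean": float(np.mean(vals) - np.mean(mrna)) if mrna.size else np.nan,
            "p_vs_mrna": wilcoxon_ranksum(vals, mrna) if mrna.size else np.nan,
        })
    return per_transcript, pd.DataFrame(test_rows)
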