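"""Stop counts to reactivity: log2 treated/control ratio, flooring, 90% Winsorising.

Raw reactivity at position i is

    r_i = max(0, log2( ((t_i + c0)/T) / ((n_i + c0)/N) ))

where t and n are treated and non-treated stop counts, c0 a pseudocount, and
T, N the per-transcript totals of the pseudocounted counts.  Per-transcript
count normalization makes the score abundance-independent; flooring reflects
that positions where the control exceeds the treatment carry no structural
signal.  Normalization is 90% Winsorising: values above the 90th percentile
are capped at it, then everything is divided by it, giving a 0-1 scale.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from .counting import filter_positions_by_depth
from .types import ReactivityProfile, StopCountTable, TranscriptRecord

DMS_CANONICAL = frozenset("AC")   # DMS methylates N1-A and N3-C
CMCT_CANONICAL = frozenset("GU")  # CMCT modifies N3-U and, weakly, N1-G


def raw_reactivity(treated: StopCountTable, control: StopCountTable,
                   pseudocount: float = 1.0, mask=None) -> np.ndarray:
    """Floored log2 ratio of per-transcript-normalized stop counts.

    Masked positions get NaN.  ``control`` is the non-treated (NT) sample.
    """
    if treated.length != control.length:
        raise ValueError("treated and control tables have different lengths")
    if treated.length == 0:
        raise ValueError("zero-length transcript")
    t = treated.stops.astype(float) + pseudocount
    c = control.stops.astype(float) + pseudocount
    ratio = (t / t.sum()) / (c / c.sum())
    r = np.maximum(0.0, np.log2(ratio))
    if mask is not None:
        r = r.copy()
        r[np.asarray(mask, dtype=bool)] = np.nan
    return r


def winsorize_normalize(raw: np.ndarray, percentile: float = 90.0) -> np.ndarray:
    """90% Winsorising: cap values above the chosen percentile at it, then
    divide by it.  NaNs (masked positions) pass through as NaN; an all-zero
    profile stays all-zero (with a warning) rather than dividing by zero.
    """
    raw = np.asarray(raw, dtype=float)
    finite = raw[~np.isnan(raw)]
    if finite.size == 0:
        return raw.copy()
    if (finite < 0).any():
        raise ValueError("raw reactivities must be non-negative")
    p = np.percentile(finite, percentile)  # linear interpolation (type-7)
    if p <= 0:
        warnings.warn("degenerate profile: normalization percentile is 0, leaving values at 0")
        return raw.copy()
    return np.minimum(raw, p) / p


def combine_channels(norm_dms: np.ndarray, norm_cmct: np.ndarray, sequence: str,
                     mode: str = "max") -> np.ndarray:
    """Combine DMS and CMCT normalized tracks into one reactivity track.

    mode "max" takes the larger available value at each position, exploiting
    the non-canonical reactivity of both reagents; mode "canonical" routes
    A/C through DMS and G/U through CMCT only.
    """
    norm_dms = np.asarray(norm_dms, dtype=float)
    norm_cmct = np.asarray(norm_cmct, dtype=float)
    if not (norm_dms.size == norm_cmct.size == len(sequence)):
        raise ValueError("channel/sequence length mismatch")
    if mode == "max":
        both = np.stack([norm_dms, norm_cmct])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            return np.nanmax(both, axis=0)
    if mode == "canonical":
        out = np.full(norm_dms.size, np.nan)
        for i, base in enumerate(sequence):
            if base in DMS_CANONICAL:
                out[i] = norm_dms[i]
            elif base in CMCT_CANONICAL:
                out[i] = norm_cmct[i]
        return out
    raise ValueError(f"unknown combination mode {mode!r}")


def classify(value) -> str | None:
    """Reactivity class: 0 unreactive, (0, 0.3) weak, [0.3, 0.7] moderate,
    (0.7, 1] high.  NaN (missing) returns None."""
    if value is None or np.isnan(value):
        return None
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"reactivity {value} outside [0, 1]")
    if value == 0.0:
        return "unreactive"
    if value < 0.3:
        return "weak"
    if value <= 0.7:
        return "moderate"
    return "high"


def compute_profile(transcript: TranscriptRecord, dms: StopCountTable, cmct: StopCountTable,
                    nt: StopCountTable, pseudocount: float = 1.0, percentile: float = 90.0,
                    mode: str = "max", min_depth: int = 50) -> ReactivityProfile:
    """Full stop-counts-to-reactivity pipeline for one transcript.

    Masks low-depth positions (depth <= min_depth in any sample), N bases, and
    the two unassignable terminal positions: a stop at position 1 has no
    upstream residue to attribute it to in this convention's inverse (reads
    starting at 1 carry no stop), and a stop at the last base would require a
    read starting past the transcript end.
    """
    n = transcript.length
    unmasked = filter_positions_by_depth(dms, cmct, nt, min_depth=min_depth)
    mask = ~unmasked
    mask[0] = True
    mask[-1] = True
    mask |= np.frombuffer(transcript.sequence.encode(), dtype=np.uint8) == ord("N")

    raw_d = raw_reactivity(dms, nt, pseudocount=pseudocount)
    raw_c = raw_reactivity(cmct, nt, pseudocount=pseudocount)
    masked_d = np.where(mask, np.nan, raw_d)
    masked_c = np.where(mask, np.nan, raw_c)
    norm_d = winsorize_normalize(masked_d, percentile=percentile)
    norm_c = winsorize_normalize(masked_c, percentile=percentile)
    combined = combine_channels(norm_d, norm_c, transcript.sequence, mode=mode)
    return ReactivityProfile(
        transcript_id=transcript.id,
        raw_dms=raw_d, raw_cmct=raw_c,
        norm_dms=norm_d, norm_cmct=norm_c,
        combined=combined, mask=mask,
    )


def average_replicates(tables) -> StopCountTable:
    """Combine replicate StopCountTables by averaging counts element-wise.

    Averaging counts (rounded to integers) rather than averaging reactivities
    preserves count statistics for the downstream log-ratio.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("no tables to combine")
    tid, sample, n = tables[0].transcript_id, tables[0].sample, tables[0].length
    for t in tables[1:]:
        if (t.transcript_id, t.sample, t.length) != (tid, sample, n):
            raise ValueError("replicates must share transcript, sample and length")
    stops = np.rint(np.mean([t.stops for t in tables], axis=0)).astype(np.int64)
    depth = np.rint(np.mean([t.depth for t in tables], axis=0)).astype(np.int64)
    return StopCountTable(transcript_id=tid, sample=sample, stops=stops,
                          depth=np.maximum(depth, stops))


def replicate_agreement(profiles_a, profiles_b, window: int = 10, offset: int = 5):
    """Pearson correlation of windowed mean reactivities between two replicates.

    Both arguments map transcript_id to a combined reactivity track (array or
    ReactivityProfile).  Reactivities are averaged in ``window``-nucleotide
    windows advanced by ``offset``; windows with data in both replicates are
    paired.  Returns (r, n_windows).
    """
    xs, ys = [], []
    for tid, a in profiles_a.items():
        if tid not in profiles_b:
            continue
        va = a.combined if isinstance(a, ReactivityProfile) else np.asarray(a, dtype=float)
        b = profiles_b[tid]
        vb = b.combined if isinstance(b, ReactivityProfile) else np.asarray(b, dtype=float)
        if va.size != vb.size:
            raise ValueError(f"transcript {tid}: replicate length mismatch")
        for start in range(0, va.size - window + 1, offset):
            wa = va[start:start + window]
            wb = vb[start:start + window]
            if np.isnan(wa).all() or np.isnan(wb).all():
                continue
            xs.append(np.nanmean(wa))
            ys.append(np.nanmean(wb))
    if len(xs) < 3:
        raise ValueError(f"only {len(xs)} shared windows; need at least 3")
    r, _ = stats.pearsonr(xs, ys)
    return float(r), len(xs)


def paired_unpaired_auc(profiles, structures) -> float:
    """AUROC of combined reactivity for discriminating unpaired from paired
    positions, over all unmasked positions of the given transcripts.

    Computed from the Mann-Whitney U statistic: AUC = U / (n1 * n0).
    """
    scores, labels = [], []
    for p in profiles:
        ss = structures[p.transcript_id]
        unpaired = ss.unpaired_mask()
        ok = ~p.mask & ~np.isnan(p.combined)
        scores.append(p.combined[ok])
        labels.append(unpaired[ok])
    scores = np.concatenate(scores)
    labels = np.concatenate(labels)
    n1, n0 = int(labels.sum()), int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("need both paired and unpaired positions")
    u = stats.mannwhitneyu(scores[labels], scores[~labels], alternative="two-sided").statistic
    return float(u / (n1 * n0))
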