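"""Reactivity around protein-binding-site summits, and motif strandedness.

Summit profiles average combined reactivity across a 300-nt window around
CLIP peak summits (offsets -150..+149, summit at 0); motif strandedness asks
how single-stranded a binding motif is in a predicted structure and whether
it sits entirely within a hairpin loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import ReactivityProfile, SecondaryStructure


@dataclass(frozen=True)
class PeakRecord:
    """A binding-site summit in transcript coordinates (1-based)."""

    transcript_id: str
    summit: int
    score: float | None = None


def summit_profile(peaks, profiles, halfwidth: int = 150) -> pd.DataFrame:
    """Mean combined reactivity per offset in [-halfwidth, halfwidth) around
    summits.  Peaks near transcript ends contribute truncated windows; a peak
    listed twice counts twice.

    Returns a tidy frame: offset, mean, n.
    """
    prof = {p.transcript_id: p for p in profiles}
    offsets = np.arange(-halfwidth, halfwidth)
    sums = np.zeros(offsets.size)
    ns = np.zeros(offsets.size, dtype=int)
    used = 0
    for peak in peaks:
        p = prof.get(peak.transcript_id)
        if p is None:
            continue
        if not (1 <= peak.summit <= p.length):
            raise ValueError(f"summit {peak.summit} outside transcript {peak.transcript_id}")
        used += 1
        pos = peak.summit + offsets
        valid = (pos >= 1) & (pos <= p.length)
        vals = p.combined[np.clip(pos, 1, p.length) - 1]
        ok = valid & ~np.isnan(vals)
        sums[ok] += vals[ok]
        ns[ok] += 1
    if used == 0:
        raise ValueError("no peaks on transcripts with profiles")
    mean = np.where(ns > 0, sums / np.maximum(ns, 1), np.nan)
    return pd.DataFrame({"offset": offsets, "mean": mean, "n": ns})


def hairpin_loops(structure: SecondaryStructure) -> list[tuple[int, int]]:
    """1-based (start, end) spans of hairpin loops: the unpaired region
    enclosed by a pair that encloses no other pair."""
    partner = structure.partner_array()
    loops = []
    for i, j in sorted(structure.pairs):
        if np.all(partner[i:j - 1] < 0):  # 0-based slice of interior i+1..j-1
            loops.append((i + 1, j - 1))
    return loops


def motif_strandedness(motif_sites, structures, profiles) -> pd.DataFrame:
    """Single-strandedness report per motif site.

    ``motif_sites`` is an iterable of (transcript_id, start, end), 1-based
    inclusive; ``structures`` and ``profiles`` map transcript_id to a
    SecondaryStructure / ReactivityProfile (or combined track).  Sites whose
    transcript lacks a structure, or that fall outside it, are skipped with
    ``usable`` False.

    Columns: transcript_id, start, end, usable, fraction_unpaired,
    in_hairpin_loop, mean_reactivity.
    """
    rows = []
    for tid, start, end in motif_sites:
        row = {"transcript_id": tid, "start": start, "end": end, "usable": False,
               "fraction_unpaired": np.nan, "in_hairpin_loop": False,
               "mean_reactivity": np.nan}
        ss = structures.get(tid)
        if ss is None or not (1 <= start <= end <= ss.length):
            rows.append(row)
            continue
        unpaired = ss.unpaired_mask()[start - 1:end]
        row["usable"] = True
        row["fraction_unpaired"] = float(np.mean(unpaired))
        row["in_hairpin_loop"] = any(ls <= start and end <= le for ls, le in hairpin_loops(ss))
        prof = profiles.get(tid) if profiles is not None else None
        if prof is not None:
            track = prof.combined if isinstance(prof, ReactivityProfile) else np.asarray(prof, dtype=float)
            vals = track[start - 1:end]
            if (~np.isnan(vals)).any():
                row["mean_reactivity"] = float(np.nanmean(vals))
        rows.append(row)
    return pd.DataFrame(rows)
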