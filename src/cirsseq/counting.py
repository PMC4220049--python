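"""RT-stop counting from read alignments, and coverage filters.

A reverse transcriptase that hits a DMS/CMCT adduct terminates one nucleotide
3' of the modified residue, so a read whose leftmost aligned base is p marks a
stop at p-1.  Reads starting at position 1 carry no assignable stop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .types import StopCountTable, TranscriptRecord


@dataclass(frozen=True)
class AlignmentRecord:
    """Minimal alignment: leftmost aligned (non-clipped) position, 1-based."""

    transcript_id: str
    left: int
    aligned_length: int

    def __post_init__(self):
        if self.left < 1 or self.aligned_length < 1:
            raise ValueError("alignment must have left >= 1 and aligned_length >= 1")


def count_stops(alignments, transcript: TranscriptRecord, sample: str = "NT") -> StopCountTable:
    """Count per-position RT stops and read depth for one transcript.

    A read with leftmost aligned position p contributes one stop at p-1 (the
    inferred modified residue).  depth[i] counts reads informative about i:
    the aligned span plus, for p > 1, the inferred modified base at p-1 —
    which keeps every stop supported by its own read's depth
    (stops[i] <= depth[i] at every position).
    """
    n = transcript.length
    stops = np.zeros(n, dtype=np.int64)
    depth_diff = np.zeros(n + 1, dtype=np.int64)
    for a in alignments:
        if a.transcript_id != transcript.id:
            raise ValueError(f"alignment on {a.transcript_id!r}, expected {transcript.id!r}")
        right = a.left + a.aligned_length - 1
        if right > n:
            raise ValueError(f"alignment [{a.left}, {right}] outside transcript {transcript.id} (length {n})")
        if a.left > 1:
            stops[a.left - 2] += 1
        cover_start = max(a.left - 1, 1)
        depth_diff[cover_start - 1] += 1
        depth_diff[right] -= 1
    depth = np.cumsum(depth_diff[:-1])
    return StopCountTable(transcript_id=transcript.id, sample=sample, stops=stops, depth=depth)


def read_sam_alignments(sam_path) -> dict[str, list[AlignmentRecord]]:
    """Read mapped reads from a SAM file into per-transcript AlignmentRecords.

    Only the reference name, leftmost aligned position and reference span are
    used; soft-clipped bases do not shift the leftmost aligned coordinate.
    """
    import pysam

    out: dict[str, list[AlignmentRecord]] = {}
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped:
                continue
            rec = AlignmentRecord(
                transcript_id=read.reference_name,
                left=read.reference_start + 1,
                aligned_length=read.reference_end - read.reference_start,
            )
            out.setdefault(rec.transcript_id, []).append(rec)
    return out


def filter_transcripts_by_stop_density(tables, transcripts, min_avg: float = 1.0) -> list[str]:
    """Retain transcripts with at least ``min_avg`` RT stops per base in each treatment.

    ``tables`` maps (transcript_id, sample) to StopCountTable.  Both the DMS
    and the CMCT sample must individually reach the density threshold.
    """
    retained = []
    for t in transcripts:
        dms = tables.get((t.id, "DMS"))
        cmct = tables.get((t.id, "CMCT"))
        if dms is None or cmct is None:
            warnings.warn(f"transcript {t.id}: missing DMS or CMCT sample, excluded")
            continue
        if dms.stops.sum() / t.length >= min_avg and cmct.stops.sum() / t.length >= min_avg:
            retained.append(t.id)
    return retained


def filter_positions_by_depth(dms: StopCountTable, cmct: StopCountTable, nt: StopCountTable,
                              min_depth: int = 50) -> np.ndarray:
    """Boolean array, True where depth is strictly greater than ``min_depth``
    in all three samples."""
    if not (dms.length == cmct.length == nt.length):
        raise ValueError("sample tables have mismatched lengths")
    return (dms.depth > min_depth) & (cmct.depth > min_depth) & (nt.depth > min_depth)
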