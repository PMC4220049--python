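"""Synthetic probing data with the statistical structure the method assumes.

Transcripts are chains of hairpin units (stems 4-10 bp, loops 4-8 nt) joined
by unpaired linkers, so ground-truth pairing is known exactly.  Stop counts
are Poisson: in a treated channel the per-position stop rate is the natural
RT-stop background plus a modification rate that is high at unpaired bases,
low at paired bases, canonical-base specific (DMS: A/C, CMCT: G/U; other
bases are scaled down), while the non-treated control sees the background
alone.  Planted effects (UTR depression, frame-1 boost, biotype shift,
summit bump) are expressed on the normalized 0-1 reactivity scale and
planted structurally: an effect of size e switches the pairing-status stop
rate of a calibrated fraction of positions in the affected region (paired
positions behave as unpaired for boosts, unpaired as paired for
depressions), so the region's mean normalized reactivity moves by
approximately e.  A mixture shift survives both the log transform and the
Winsorising cap, which clip smooth rate scalings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .counting import AlignmentRecord
from .types import SecondaryStructure, StopCountTable, TranscriptRecord

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


@dataclass
class SimParams:
    """Generator settings; probabilities are per position per read."""

    n_transcripts: int = 100
    length_range: tuple = (60, 120)
    depth: float = 1000.0                # mean coverage, constant along a transcript
    p_mod_unpaired: float = 0.15         # modification-stop rate, unpaired canonical base
    p_mod_paired: float = 0.01
    noncanonical_scale: float = 0.3      # rate multiplier at non-canonical bases
    p_natural: float = 0.005             # natural RT-stop rate (also the NT rate)
    gu_rate: float = 0.1                 # chance a stem pair is G-U rather than Watson-Crick
    seed: int = 0
    # planted effects, on the normalized-reactivity scale (0 disables)
    utr_depression: float = 0.0
    frame1_boost: float = 0.0
    biotype_shift: float = 0.0
    summit_bump: float = 0.0

    def __post_init__(self):
        for name in ("p_mod_unpaired", "p_mod_paired", "p_natural"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.p_mod_unpaired < self.p_mod_paired:
            raise ValueError("p_mod_unpaired must be at least p_mod_paired")

    @property
    def log2_dynamic_range(self) -> float:
        """log2 ratio between the treated rate at an unpaired canonical base
        and the background; the scale of raw reactivities."""
        return math.log2((self.p_natural + self.p_mod_unpaired) / self.p_natural)

    @property
    def reactivity_gap(self) -> float:
        """A-priori estimate of the normalized-reactivity gap between
        unpaired and paired canonical positions, used to calibrate how many
        positions a planted effect must flip to move a region's mean by the
        nominal amount."""
        paired_log2 = math.log2((self.p_natural + self.p_mod_paired) / self.p_natural)
        return (self.log2_dynamic_range - paired_log2) / self.log2_dynamic_range


# ---------------------------------------------------------------------------
# transcript and structure generation

def hairpin_unit(stem: int, loop: int, rng: np.random.Generator, gu_rate: float = 0.1):
    """One hairpin: (sequence, dot-bracket).  Stem bases are complementary,
    with G-U wobbles at the given rate."""
    left = rng.choice(list("ACGU"), size=stem)
    right = []
    for b in left[::-1]:
        c = _COMPLEMENT[b]
        if b in "GU" and rng.random() < gu_rate:
            c = "U" if b == "G" else "G"
        right.append(c)
    loop_seq = rng.choice(list("ACGU"), size=loop)
    seq = "".join(left) + "".join(loop_seq) + "".join(right)
    db = "(" * stem + "." * loop + ")" * stem
    return seq, db


def make_structured_transcript(params: SimParams, seed, length: int | None = None,
                               transcript_id: str = "t", biotype: str = "other"):
    """Generate one transcript as hairpins joined by unpaired linkers.

    Returns (TranscriptRecord, SecondaryStructure).  The sequence is
    consistent with the structure (complementary stems).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if length is None:
        length = int(rng.integers(params.length_range[0], params.length_range[1] + 1))
    if length < 30:
        raise ValueError("transcript length must be >= 30")

    seq_parts, db_parts = [], []
    pos = 0
    # leading linker
    link = int(rng.integers(3, 9))
    seq_parts.append("".join(rng.choice(list("ACGU"), size=link)))
    db_parts.append("." * link)
    pos += link
    while True:
        stem = int(rng.integers(4, 11))
        loop = int(rng.integers(4, 9))
        link = int(rng.integers(3, 9))
        unit_len = 2 * stem + loop + link
        if pos + unit_len > length:
            break
        s, d = hairpin_unit(stem, loop, rng, params.gu_rate)
        seq_parts.append(s)
        db_parts.append(d)
        seq_parts.append("".join(rng.choice(list("ACGU"), size=link)))
        db_parts.append("." * link)
        pos += unit_len
    if pos < length:  # pad to exact length with linker
        pad = length - pos
        seq_parts.append("".join(rng.choice(list("ACGU"), size=pad)))
        db_parts.append("." * pad)

    from .io import dotbracket_to_pairs

    sequence = "".join(seq_parts)
    structure = dotbracket_to_pairs("".join(db_parts), transcript_id)
    record = TranscriptRecord(id=transcript_id, sequence=sequence, biotype=biotype)
    return record, structure


def make_mrna(params: SimParams, seed, transcript_id: str = "m",
              utr5_range=(60, 90), n_codon_range=(70, 110), utr3_range=(60, 90)):
    """Generate an mRNA-like transcript: CDS (AUG...stop) placed on unpaired
    linker positions of a structured transcript, flanked by UTRs.

    Returns (TranscriptRecord with CDS annotation, SecondaryStructure).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    for _ in range(8):  # placement can rarely fail on an unlucky structure
        utr5 = int(rng.integers(*utr5_range))
        n_codons = int(rng.integers(*n_codon_range))
        utr3 = int(rng.integers(*utr3_range))
        length = utr5 + 3 * n_codons + utr3
        rec, ss = make_structured_transcript(params, rng, length=length, transcript_id=transcript_id)
        unpaired = ss.unpaired_mask()
        triple_ok = unpaired[:-2] & unpaired[1:-1] & unpaired[2:]
        starts = np.flatnonzero(triple_ok) + 1  # 1-based first base of an unpaired triple
        cand_start = starts[(starts >= 57) & (starts <= length - 3 * 60 - 50)]
        if cand_start.size == 0:
            continue
        cds_start = int(cand_start[np.argmin(np.abs(cand_start - (utr5 + 1)))])
        ends = starts + 2  # 1-based last base of an unpaired triple
        cand_end = ends[((ends - cds_start + 1) % 3 == 0)
                        & (ends >= cds_start + 3 * 60 - 1)
                        & (ends <= length - 50)]
        if cand_end.size == 0:
            continue
        desired_end = cds_start + 3 * n_codons - 1
        cds_end = int(cand_end[np.argmin(np.abs(cand_end - desired_end))])
        seq = list(rec.sequence)
        seq[cds_start - 1:cds_start + 2] = "AUG"
        seq[cds_end - 3:cds_end] = "UAA"
        record = TranscriptRecord(id=transcript_id, sequence="".join(seq),
                                  cds_start=cds_start, cds_end=cds_end, biotype="mRNA")
        return record, ss
    raise RuntimeError("could not place a CDS on generated structures")


# ---------------------------------------------------------------------------
# planted effects and count simulation

def effect_track(transcript: TranscriptRecord, params: SimParams,
                 summits=None) -> np.ndarray | None:
    """Per-position planted effect on the normalized-reactivity scale.

    Negative values depress reactivity.  Returns None when no effect is
    active for this transcript.
    """
    n = transcript.length
    s = np.zeros(n)
    active = False
    if params.utr_depression and transcript.has_cds:
        pos = np.arange(1, n + 1)
        s[(pos < transcript.cds_start) | (pos > transcript.cds_end)] -= params.utr_depression
        active = True
    if params.frame1_boost and transcript.has_cds:
        pos = np.arange(1, n + 1)
        in_cds = (pos >= transcript.cds_start) & (pos <= transcript.cds_end)
        frame1 = (pos - transcript.cds_start) % 3 == 0
        s[in_cds & frame1] += params.frame1_boost
        active = True
    if params.biotype_shift and transcript.biotype != "mRNA":
        s -= params.biotype_shift
        active = True
    if params.summit_bump and summits:
        pos = np.arange(1, n + 1)
        for summit in summits:
            s[np.abs(pos - summit) <= 25] += params.summit_bump
        active = True
    return s if active else None


def _effective_unpaired(unpaired: np.ndarray, effects: np.ndarray | None,
                        params: SimParams, rng: np.random.Generator) -> np.ndarray:
    """Pairing-status rate mask after planting effects.

    For each region of constant nonzero effect e, a fraction
    |e| / (reactivity_gap * eligible_fraction) of the eligible positions
    (paired for e > 0, unpaired for e < 0) has its stop-rate class flipped,
    moving the region's mean normalized reactivity by about e.
    """
    if effects is None:
        return unpaired
    out = unpaired.copy()
    gap = params.reactivity_gap
    for e in np.unique(effects[effects != 0]):
        region = effects == e
        eligible = region & (unpaired if e < 0 else ~unpaired)
        frac = eligible.sum() / region.sum()
        if frac == 0:
            continue
        f = min(1.0, abs(e) / (gap * frac))
        flip = eligible & (rng.random(unpaired.size) < f)
        out[flip] = e > 0
    return out


def simulate_counts(transcript: TranscriptRecord, structure: SecondaryStructure,
                    params: SimParams, seed, effects: np.ndarray | None = None
                    ) -> dict[str, StopCountTable]:
    """Poisson stop counts for the DMS, CMCT and NT samples of one transcript.

    Depth is Poisson(params.depth), constant along the transcript.  The
    3'-terminal position never receives a stop: a stop there would imply a
    read starting past the transcript end, which cannot be observed.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = transcript.length
    unpaired = structure.unpaired_mask()
    base = np.frombuffer(transcript.sequence.encode(), dtype=np.uint8)
    depth_val = int(rng.poisson(params.depth))
    depth = np.full(n, depth_val, dtype=np.int64)
    unpaired = _effective_unpaired(unpaired, effects, params, rng)

    out = {}
    for sample, canon in (("DMS", b"AC"), ("CMCT", b"GU")):
        canonical = np.isin(base, np.frombuffer(canon, dtype=np.uint8))
        p_mod = np.where(unpaired, params.p_mod_unpaired, params.p_mod_paired)
        chan = p_mod * np.where(canonical, 1.0, params.noncanonical_scale)
        rate = np.clip(params.p_natural + chan, 0.0, 1.0)
        stops = np.minimum(rng.poisson(depth_val * rate, size=n), depth)
        stops[-1] = 0
        out[sample] = StopCountTable(transcript.id, sample, stops, depth.copy())
    nt_stops = np.minimum(rng.poisson(depth_val * params.p_natural, size=n), depth)
    nt_stops[-1] = 0
    out["NT"] = StopCountTable(transcript.id, "NT", nt_stops, depth.copy())
    return out


def simulate_reads(table: StopCountTable, seed) -> list[AlignmentRecord]:
    """Emit alignments whose count_stops output reproduces the table exactly.

    Each stop at position i yields a read with left = i+1 (whose informative
    coverage therefore begins at i); read-through reads starting at position
    1 and randomized read ends make the depth column match.  Simulator
    tables (constant depth along the transcript) are always realizable;
    arbitrary tables that no read set can explain raise an error.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = table.length
    stops, depth = table.stops, table.depth
    if n == 0:
        return []
    if stops[-1] != 0:
        raise ValueError("a stop at the 3'-terminal position is not realizable as a read")
    reads: list[AlignmentRecord] = []
    # active reads, by left coordinate; coverage of a read spans left-1..right
    # (left..right for read-through), so reads covering position c onwards are
    # those with left = c+1 (one per stop at c) plus left = 1 read-throughs.
    k = int(depth[0]) - int(stops[0])
    if k < 0:
        raise ValueError("depth at position 1 cannot support its stop count")
    active: list[int] = [1] * k + [2] * int(stops[0])
    for c in range(2, n + 1):  # 1-based coverage position
        new = int(stops[c - 1])
        n_end = len(active) + new - int(depth[c - 1])
        if n_end < 0:
            raise ValueError(f"table not realizable as reads at position {c}")
        if n_end:
            # a read may only end at c-1 if its aligned span starts by then
            eligible = [idx for idx, left in enumerate(active) if left <= c - 1]
            if len(eligible) < n_end:
                raise ValueError(f"table not realizable as reads at position {c}")
            chosen = rng.choice(len(eligible), size=n_end, replace=False)
            for k_idx in sorted((eligible[int(i)] for i in chosen), reverse=True):
                left = active.pop(k_idx)
                reads.append(AlignmentRecord(table.transcript_id, left, c - 1 - left + 1))
        active.extend([c + 1] * new)
    for left in active:
        reads.append(AlignmentRecord(table.transcript_id, left, n - left + 1))
    return reads


# ---------------------------------------------------------------------------
# dataset-level convenience

def simulate_dataset(params: SimParams, mrna: bool = False, biotypes=None):
    """Simulate a full dataset under ``params``.

    Returns (transcripts, structures, counts) with counts keyed by
    (transcript_id, sample).  With ``mrna=True`` transcripts are mRNA-like
    with CDS annotation; ``biotypes`` optionally cycles biotype labels over
    the (non-mRNA) transcripts.
    """
    root = np.random.default_rng(params.seed)
    transcripts, structures, counts = [], {}, {}
    for k in range(params.n_transcripts):
        tid = f"sim{k:04d}"
        sub = np.random.default_rng(root.integers(2 ** 31))
        if mrna:
            rec, ss = make_mrna(params, sub, transcript_id=tid)
        else:
            biotype = biotypes[k % len(biotypes)] if biotypes else "other"
            rec, ss = make_structured_transcript(params, sub, transcript_id=tid, biotype=biotype)
        eff = effect_track(rec, params)
        for sample, table in simulate_counts(rec, ss, params, sub, effects=eff).items():
            counts[(tid, sample)] = table
        transcripts.append(rec)
        structures[tid] = ss
    return transcripts, structures, counts
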