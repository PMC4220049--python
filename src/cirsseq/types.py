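"""Core domain types shared by every pipeline stage.

All coordinates are 1-based, inclusive, and live in transcript space: the
conventions of CT and SHAPE files, and the natural frame for per-transcript
probing analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VALID_BASES = set("ACGUN")
BIOTYPES = ("mRNA", "lincRNA", "snoRNA", "snRNA", "tRNA", "other")


@dataclass
class TranscriptRecord:
    """One transcript: RNA sequence plus optional CDS annotation and biotype.

    The 5' UTR is ``[1, cds_start-1]``, the CDS ``[cds_start, cds_end]``
    (including the stop codon), and the 3' UTR ``[cds_end+1, length]``.
    """

    id: str
    sequence: str
    cds_start: int | None = None
    cds_end: int | None = None
    biotype: str = "other"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"transcript {self.id}: empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(f"transcript {self.id}: invalid bases {sorted(bad)}")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"transcript {self.id}: unknown biotype {self.biotype!r}")
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(f"transcript {self.id}: cds_start/cds_end must both be set or both absent")
        if self.cds_start is not None:
            if not (1 <= self.cds_start <= self.cds_end <= self.length):
                raise ValueError(
                    f"transcript {self.id}: CDS [{self.cds_start}, {self.cds_end}] "
                    f"outside sequence of length {self.length}"
                )
            if (self.cds_end - self.cds_start + 1) % 3 != 0:
                raise ValueError(f"transcript {self.id}: CDS span not divisible by 3")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def has_cds(self) -> bool:
        return self.cds_start is not None


@dataclass
class StopCountTable:
    """Per-position RT-stop counts and read depth for one transcript, one sample.

    ``sample`` is one of DMS, CMCT (treated channels) or NT (non-treated
    control capturing naturally occurring RT stops).
    """

    transcript_id: str
    sample: str
    stops: np.ndarray
    depth: np.ndarray

    def __post_init__(self) -> None:
        if self.sample not in ("DMS", "CMCT", "NT"):
            raise ValueError(f"unknown sample {self.sample!r}")
        self.stops = np.asarray(self.stops, dtype=np.int64)
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if self.stops.shape != self.depth.shape or self.stops.ndim != 1:
            raise ValueError("stops and depth must be equal-length 1-D arrays")
        if (self.stops < 0).any() or (self.depth < 0).any():
            raise ValueError("negative counts")
        if (self.stops > self.depth).any():
            raise ValueError(f"{self.transcript_id}/{self.sample}: stops exceed depth")

    @property
    def length(self) -> int:
        return self.stops.size


@dataclass
class ReactivityProfile:
    """Raw and normalized (0-1) per-position reactivities for one transcript.

    Missing values are NaN.  ``mask`` flags positions excluded from analysis
    (low depth, the unassignable terminal positions, N bases); masked
    positions carry NaN in the normalized and combined tracks.
    """

    transcript_id: str
    raw_dms: np.ndarray
    raw_cmct: np.ndarray
    norm_dms: np.ndarray
    norm_cmct: np.ndarray
    combined: np.ndarray
    mask: np.ndarray  # True = excluded

    def __post_init__(self) -> None:
        arrs = [self.raw_dms, self.raw_cmct, self.norm_dms, self.norm_cmct, self.combined]
        arrs = [np.asarray(a, dtype=float) for a in arrs]
        self.raw_dms, self.raw_cmct, self.norm_dms, self.norm_cmct, self.combined = arrs
        self.mask = np.asarray(self.mask, dtype=bool)
        n = self.mask.size
        if any(a.size != n for a in arrs):
            raise ValueError("profile tracks must share one length")
        for a in (self.norm_dms, self.norm_cmct, self.combined):
            vals = a[~np.isnan(a)]
            if vals.size and ((vals < 0).any() or (vals > 1).any()):
                raise ValueError("normalized reactivities outside [0, 1]")
        if not np.isnan(self.combined[self.mask]).all():
            raise ValueError("masked positions must carry no combined value")

    @property
    def length(self) -> int:
        return self.mask.size


@dataclass
class SecondaryStructure:
    """A nested set of base pairs over one transcript.

    Pairs are 1-based ``(i, j)`` with ``i < j``; each position belongs to at
    most one pair; pseudoknots are rejected.  The container is permissive
    about loop sizes so external reference structures parse; the folding
    engine itself never emits a hairpin loop shorter than 3.
    """

    transcript_id: str
    pairs: frozenset
    length: int

    def __post_init__(self) -> None:
        self.pairs = frozenset((int(i), int(j)) for i, j in self.pairs)
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (1 <= i < j <= self.length):
                raise ValueError(f"pair ({i}, {j}) outside [1, {self.length}]")
            for p in (i, j):
                if p in seen:
                    raise ValueError(f"position {p} paired twice")
                seen.add(p)
        ordered = sorted(self.pairs)
        for a in range(len(ordered)):
            i, j = ordered[a]
            for k, l in ordered[a + 1:]:
                if k >= j:
                    break
                if not (l < j):  # i < k < j requires l < j for nesting
                    raise ValueError(f"crossing pairs ({i},{j}) and ({k},{l}): pseudoknots unsupported")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def partner_array(self) -> np.ndarray:
        """0-based array: partner[i] = 0-based partner of position i+1, or -1."""
        partner = np.full(self.length, -1, dtype=np.int64)
        for i, j in self.pairs:
            partner[i - 1] = j - 1
            partner[j - 1] = i - 1
        return partner

    def unpaired_mask(self) -> np.ndarray:
        return self.partner_array() < 0
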