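"""Readers and writers for the formats the pipeline touches.

FASTA (transcripts, via Biopython), flat TSV (CDS/biotype annotation, count
tables, reactivity tables, peaks), dot-bracket and 6-column CT (structures),
and the two-column SHAPE reactivity format with its -999 missing-value
sentinel.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .types import StopCountTable, SecondaryStructure, TranscriptRecord


# ---------------------------------------------------------------------------
# transcripts

def read_transcripts(fasta_path, annotation_path=None) -> list[TranscriptRecord]:
    """Load transcripts from FASTA, joining optional CDS/biotype annotation by id.

    DNA input is accepted: T is converted to U.  Unannotated transcripts get
    biotype "other" and no CDS.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate transcript id {rec.id!r} in {fasta_path}")
        seqs[rec.id] = str(rec.seq).upper().replace("T", "U")

    annot: dict[str, dict] = {}
    if annotation_path is not None:
        df = pd.read_csv(annotation_path, sep="\t", dtype={"id": str})
        for _, row in df.iterrows():
            tid = row["id"]
            if tid not in seqs:
                warnings.warn(f"annotation for unknown transcript {tid!r} skipped")
                continue
            cs = row.get("cds_start")
            ce = row.get("cds_end")
            annot[tid] = {
                "cds_start": None if pd.isna(cs) else int(cs),
                "cds_end": None if pd.isna(ce) else int(ce),
                "biotype": row.get("biotype", "other") if not pd.isna(row.get("biotype")) else "other",
            }

    records = []
    for tid, seq in seqs.items():
        a = annot.get(tid, {})
        records.append(TranscriptRecord(id=tid, sequence=seq, **a))
    return records


def write_transcripts(records, fasta_path, annotation_path=None) -> None:
    with open(fasta_path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n{r.sequence}\n")
    if annotation_path is not None:
        rows = [
            {"id": r.id, "cds_start": r.cds_start, "cds_end": r.cds_end, "biotype": r.biotype}
            for r in records
        ]
        pd.DataFrame(rows).to_csv(annotation_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# structures

def dotbracket_to_pairs(db_string: str, transcript_id: str = "") -> SecondaryStructure:
    """Parse a dot-bracket string into a nested pair set (1-based)."""
    pairs = []
    stack = []
    for pos, ch in enumerate(db_string, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {pos}")
            pairs.append((stack.pop(), pos))
        elif ch != ".":
            raise ValueError(f"invalid character {ch!r} at position {pos}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return SecondaryStructure(transcript_id=transcript_id, pairs=frozenset(pairs), length=len(db_string))


def pairs_to_dotbracket(structure: SecondaryStructure) -> str:
    out = ["."] * structure.length
    for i, j in structure.pairs:
        out[i - 1] = "("
        out[j - 1] = ")"
    return "".join(out)


def write_ct(structure: SecondaryStructure, sequence: str, path) -> None:
    """Write standard 6-column CT (index, base, i-1, i+1, partner or 0, index)."""
    if len(sequence) != structure.length:
        raise ValueError("sequence length does not match structure length")
    partner = structure.partner_array()
    with open(path, "w") as fh:
        fh.write(f"{structure.length} {structure.transcript_id or 'structure'}\n")
        for i in range(1, structure.length + 1):
            nxt = i + 1 if i < structure.length else 0
            fh.write(f"{i} {sequence[i - 1]} {i - 1} {nxt} {partner[i - 1] + 1} {i}\n")


def read_ct(path) -> tuple[SecondaryStructure, str]:
    """Read a 6-column CT file; returns (structure, sequence)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"empty CT file {path}")
    n = int(lines[0].split()[0])
    title = lines[0].split(maxsplit=1)[1] if len(lines[0].split()) > 1 else ""
    partner = np.zeros(n + 1, dtype=int)
    seq = []
    for line in lines[1:n + 1]:
        f = line.split()
        i, base, pj = int(f[0]), f[1], int(f[4])
        seq.append(base)
        partner[i] = pj
    pairs = set()
    for i in range(1, n + 1):
        j = partner[i]
        if j == 0:
            continue
        if partner[j] != i:
            raise ValueError(f"CT reciprocity violated: {i} pairs {j} but {j} pairs {partner[j]}")
        if i < j:
            pairs.add((i, j))
    return (
        SecondaryStructure(transcript_id=title, pairs=frozenset(pairs), length=n),
        "".join(seq),
    )


# ---------------------------------------------------------------------------
# SHAPE reactivity files

SHAPE_MISSING = -999.0


def write_shape(values, path) -> None:
    """Write a two-column SHAPE file; NaN/masked values become -999."""
    values = np.asarray(values, dtype=float)
    with open(path, "w") as fh:
        for pos, v in enumerate(values, start=1):
            if np.isnan(v):
                fh.write(f"{pos} -999\n")
            else:
                fh.write(f"{pos} {v:.4f}\n")


def read_shape(path) -> np.ndarray:
    """Read a two-column SHAPE file; -999 becomes NaN.  Positions must ascend."""
    positions, values = [], []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        p, v = line.split()
        positions.append(int(p))
        values.append(float(v))
    if positions != list(range(1, len(positions) + 1)):
        raise ValueError(f"non-monotonic or gapped positions in {path}")
    out = np.array(values, dtype=float)
    out[out <= SHAPE_MISSING] = np.nan
    return out


# ---------------------------------------------------------------------------
# count and reactivity tables (long-format TSV)

COUNT_COLUMNS = ["transcript_id", "position", "sample", "stops", "depth"]


def write_count_tables(tables, path) -> None:
    """Write StopCountTables as long TSV (transcript_id, position, sample, stops, depth)."""
    frames = []
    for t in tables:
        frames.append(pd.DataFrame({
            "transcript_id": t.transcript_id,
            "position": np.arange(1, t.length + 1),
            "sample": t.sample,
            "stops": t.stops,
            "depth": t.depth,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_count_tables(path) -> dict[tuple[str, str], StopCountTable]:
    """Read long-format count TSV into {(transcript_id, sample): StopCountTable}."""
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"count table missing columns {sorted(missing)}")
    out = {}
    for (tid, sample), grp in df.groupby(["transcript_id", "sample"], sort=False):
        grp = grp.sort_values("position")
        n = int(grp["position"].max())
        if list(grp["position"]) != list(range(1, n + 1)):
            raise ValueError(f"{tid}/{sample}: positions not contiguous from 1")
        out[(tid, sample)] = StopCountTable(
            transcript_id=tid, sample=sample,
            stops=grp["stops"].to_numpy(), depth=grp["depth"].to_numpy(),
        )
    return out


def write_reactivity_table(profiles, transcripts, path) -> None:
    """Write per-position reactivity TSV for a set of profiles.

    Columns: transcript_id, position, base, raw_dms, raw_cmct, norm_dms,
    norm_cmct, combined, class.
    """
    from .reactivity import classify

    seq_by_id = {t.id: t.sequence for t in transcripts}
    frames = []
    for p in profiles:
        seq = seq_by_id[p.transcript_id]
        cls = [classify(v) or "" for v in p.combined]
        frames.append(pd.DataFrame({
            "transcript_id": p.transcript_id,
            "position": np.arange(1, p.length + 1),
            "base": list(seq),
            "raw_dms": np.round(p.raw_dms, 6),
            "raw_cmct": np.round(p.raw_cmct, 6),
            "norm_dms": np.round(p.norm_dms, 6),
            "norm_cmct": np.round(p.norm_cmct, 6),
            "combined": np.round(p.combined, 6),
            "class": cls,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_reactivity_table(path) -> dict[str, "np.ndarray"]:
    """Read the combined track back from a reactivity TSV: {transcript_id: array}."""
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str}, na_values=["NA"])
    out = {}
    for tid, grp in df.groupby("transcript_id", sort=False):
        grp = grp.sort_values("position")
        out[tid] = grp["combined"].to_numpy(dtype=float)
    return out


def read_peaks(path):
    """Read a BED-like peaks TSV into PeakRecords.

    Accepts either a ``summit`` column directly, or ``start`` plus
    ``summit_offset`` (summit = start + summit_offset); ``score`` is optional.
    """
    from .peaks import PeakRecord

    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
    peaks = []
    for _, row in df.iterrows():
        if "summit" in df.columns:
            summit = int(row["summit"])
        elif {"start", "summit_offset"} <= set(df.columns):
            summit = int(row["start"]) + int(row["summit_offset"])
        else:
            raise ValueError("peaks file needs a 'summit' column or 'start' + 'summit_offset'")
        score = float(row["score"]) if "score" in df.columns and not pd.isna(row.get("score")) else None
        peaks.append(PeakRecord(transcript_id=row["transcript_id"], summit=summit, score=score))
    return peaks
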