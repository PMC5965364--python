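"""Read QC, host-read removal, duplicate removal and sample-selection filters.

The mapper here is deliberately small: exact-seed lookup followed by
ungapped full-length extension, reporting a read only at its unique best
placement. It is sufficient for synthetic indel-free reads; for real data a
production aligner's SAM output can be imported instead
(:func:`read_sam_alignments`).

Coordinates are 0-based half-open throughout; mismatch read positions are
1-based from the read's 5' end (the misincorporation-profile convention).
"""

from __future__ import annotations

import gzip
import json
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._seq import revcomp, seq_to_u8
from .records import AlignmentRecord, ReadRecord


def read_fastq(path) -> Iterator[ReadRecord]:
    """Stream FASTQ(.gz) records; malformed records raise a parse error
    carrying the record index."""
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "rt") as fh:
        idx = 0
        try:
            for rec in SeqIO.parse(fh, "fastq"):
                quals = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
                yield ReadRecord(rec.id, str(rec.seq).upper(), quals)
                idx += 1
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ record at index {idx}: {exc}") from exc


def quality_trim_filter(
    reads: Iterable[ReadRecord], min_length: int = 25, min_quality: int = 30
) -> Iterator[ReadRecord]:
    """3'-trim bases below ``min_quality`` and drop reads shorter than
    ``min_length`` after trimming; input order is preserved."""
    for read in reads:
        phred = read.phred
        end = len(phred)
        while end > 0 and phred[end - 1] < min_quality:
            end -= 1
        if end >= min_length:
            if end == len(phred):
                yield read
            else:
                yield ReadRecord(read.read_id, read.sequence[:end], read.qualities[:end])


class ReferenceIndex:
    """Exact-seed index over a set of reference sequences."""

    def __init__(self, references: Mapping[str, str], seed_length: int = 16):
        if any(len(s) == 0 for s in references.values()):
            raise ValueError("references must be non-empty sequences")
        self.seed_length = seed_length
        self.sequences = {rid: seq.upper() for rid, seq in references.items()}
        self.arrays = {rid: seq_to_u8(seq) for rid, seq in self.sequences.items()}
        self._index: dict[bytes, list[tuple[str, int]]] = defaultdict(list)
        k = seed_length
        for rid, seq in self.sequences.items():
            data = seq.encode("ascii")
            for i in range(len(data) - k + 1):
                self._index[data[i : i + k]].append((rid, i))

    def seed_hits(self, seq_bytes: bytes) -> Iterator[tuple[str, int, int]]:
        """Yield (reference, ref_pos, read_offset) exact seed matches at a
        sparse set of offsets covering the read."""
        k = self.seed_length
        L = len(seq_bytes)
        if L < k:
            return
        offsets = list(range(0, L - k + 1, k))
        if offsets[-1] != L - k:
            offsets.append(L - k)
        for off in offsets:
            for rid, pos in self._index.get(seq_bytes[off : off + k], ()):
                yield rid, pos, off


def _best_placements(
    read_seq: str, index: ReferenceIndex, max_mismatches: int
) -> tuple[int, list[tuple[str, int, str]]]:
    """All placements attaining the minimum mismatch count (<= max)."""
    L = len(read_seq)
    fwd = read_seq.encode("ascii")
    rev = revcomp(read_seq).encode("ascii")
    candidates: set[tuple[str, int, str]] = set()
    for strand, data in (("+", fwd), ("-", rev)):
        for rid, pos, off in index.seed_hits(data):
            start = pos - off
            if 0 <= start and start + L <= len(index.arrays[rid]):
                candidates.add((rid, start, strand))
    if not candidates:
        return -1, []
    fwd_arr = np.frombuffer(fwd, dtype=np.uint8)
    rev_arr = np.frombuffer(rev, dtype=np.uint8)
    best_nm = max_mismatches + 1
    best: list[tuple[str, int, str]] = []
    for rid, start, strand in candidates:
        refseg = index.arrays[rid][start : start + L]
        nm = int(np.count_nonzero(refseg != (fwd_arr if strand == "+" else rev_arr)))
        if nm < best_nm:
            best_nm, best = nm, [(rid, start, strand)]
        elif nm == best_nm:
            best.append((rid, start, strand))
    return (best_nm, best) if best_nm <= max_mismatches else (-1, [])


def _make_alignment(
    read: ReadRecord, index: ReferenceIndex, rid: str, start: int, strand: str
) -> AlignmentRecord:
    L = len(read.sequence)
    refseg = index.sequences[rid][start : start + L]
    oriented_ref = refseg if strand == "+" else revcomp(refseg)
    mismatches = tuple(
        (i + 1, rb, qb)
        for i, (rb, qb) in enumerate(zip(oriented_ref, read.sequence))
        if rb != qb
    )
    return AlignmentRecord(read.read_id, rid, start, strand, L, mismatches)


def map_reads(
    reads: Iterable[ReadRecord],
    references: Mapping[str, str] | ReferenceIndex,
    seed_length: int = 16,
    max_mismatches: int = 5,
) -> list[AlignmentRecord]:
    """Map reads by exact-seed + ungapped extension.

    A read is reported only at its unique best (fewest-mismatch) placement;
    any tie — across or within references — leaves the read unmapped.
    Unmapped reads are silently excluded (their count is the caller's QC
    concern).
    """
    index = (
        references
        if isinstance(references, ReferenceIndex)
        else ReferenceIndex(references, seed_length)
    )
    out: list[AlignmentRecord] = []
    for read in reads:
        nm, best = _best_placements(read.sequence, index, max_mismatches)
        if len(best) == 1:
            rid, start, strand = best[0]
            out.append(_make_alignment(read, index, rid, start, strand))
    return out


def map_reads_all_best(
    reads: Iterable[ReadRecord],
    references: Mapping[str, str] | ReferenceIndex,
    seed_length: int = 16,
    max_mismatches: int = 5,
) -> list[tuple[ReadRecord, list[tuple[str, int, str]]]]:
    """Like :func:`map_reads` but returns every best-scoring placement per
    read (used by marker profiling, where ties within one species are fine)."""
    index = (
        references
        if isinstance(references, ReferenceIndex)
        else ReferenceIndex(references, seed_length)
    )
    out = []
    for read in reads:
        nm, best = _best_placements(read.sequence, index, max_mismatches)
        if best:
            out.append((read, best))
    return out


def remove_host_reads(
    reads: Sequence[ReadRecord],
    host_reference: str | Mapping[str, str] | ReferenceIndex,
    seed_length: int = 16,
    max_mismatches: int = 5,
) -> tuple[list[ReadRecord], float, list[AlignmentRecord]]:
    """Split reads into (exogenous, host_fraction, host_alignments).

    ``host_fraction`` is the fraction of input reads mapping to the host
    reference. Host alignments are returned because the endogenous-DNA
    damage fit consumes them later.
    """
    if isinstance(host_reference, str):
        if not host_reference:
            raise ValueError("host reference must be non-empty")
        host_reference = {"host": host_reference}
    reads = list(reads)
    alignments = map_reads(reads, host_reference, seed_length, max_mismatches)
    host_ids = {a.read_id for a in alignments}
    exogenous = [r for r in reads if r.read_id not in host_ids]
    frac = len(host_ids) / len(reads) if reads else 0.0
    return exogenous, frac, alignments


def deduplicate(alignments: Iterable[AlignmentRecord]) -> list[AlignmentRecord]:
    """Collapse coordinate duplicates.

    Single-end records sharing (reference, start, strand, read_length) are
    PCR-duplicate candidates; the record with the smallest read_id survives.
    Idempotent; output sorted by (reference, start, strand, read_id).
    """
    best: dict[tuple, AlignmentRecord] = {}
    for a in alignments:
        key = (a.reference_id, a.ref_start, a.strand, a.read_length)
        cur = best.get(key)
        if cur is None or a.read_id < cur.read_id:
            best[key] = a
    return sorted(
        best.values(), key=lambda a: (a.reference_id, a.ref_start, a.strand, a.read_id)
    )


@dataclass
class SampleQC:
    """Per-sample quality-control counters feeding the selection filters."""

    sample_id: str
    n_raw: int
    n_filtered: int = 0
    n_host_mapped: int = 0
    host_fraction: float = 0.0
    n_marker_mapped: int = 0
    n_prokaryote_marker: int = 0
    pass_flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_filtered > self.n_raw:
            raise ValueError("n_filtered cannot exceed n_raw")
        if self.n_host_mapped > max(self.n_filtered, 0) and self.n_filtered:
            raise ValueError("n_host_mapped cannot exceed n_filtered")
        if not 0.0 <= self.host_fraction <= 1.0:
            raise ValueError("host_fraction outside [0, 1]")


def sample_selection(
    qc: Sequence[SampleQC],
    min_raw: int = 1_000_000,
    min_marker: int = 1000,
    min_prokaryote_marker: int = 1000,
) -> tuple[list[SampleQC], pd.DataFrame]:
    """Apply the three sequential sample filters.

    1. drop samples with fewer than ``min_raw`` raw reads;
    2. of the rest, drop those with fewer than ``min_marker`` reads mapped
       to taxonomic markers;
    3. of the rest, drop those with fewer than ``min_prokaryote_marker``
       reads mapped exclusively to bacterial/archaeal markers.

    Returns the passing samples and a report naming, for each rejected
    sample, the single filter that removed it.
    """
    seen: set[str] = set()
    for q in qc:
        if q.sample_id in seen:
            raise ValueError(f"duplicate sample_id {q.sample_id!r}")
        seen.add(q.sample_id)
    passing: list[SampleQC] = []
    rows = []
    for q in qc:
        if q.n_raw < min_raw:
            reason = "min_raw"
        elif q.n_marker_mapped < min_marker:
            reason = "min_marker"
        elif q.n_prokaryote_marker < min_prokaryote_marker:
            reason = "min_prokaryote_marker"
        else:
            reason = ""
        q.pass_flags = {
            "raw_ok": q.n_raw >= min_raw,
            "marker_ok": q.n_marker_mapped >= min_marker,
            "prokaryote_ok": q.n_prokaryote_marker >= min_prokaryote_marker,
        }
        if not reason:
            passing.append(q)
        rows.append(
            {"sample_id": q.sample_id, "passed": not reason, "rejected_by": reason}
        )
    report = pd.DataFrame(rows, columns=["sample_id", "passed", "rejected_by"])
    return passing, report


def qc_table(qc: Sequence[SampleQC]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": q.sample_id,
                "n_raw": q.n_raw,
                "n_filtered": q.n_filtered,
                "n_host_mapped": q.n_host_mapped,
                "host_fraction": q.host_fraction,
                "n_marker_mapped": q.n_marker_mapped,
                "n_prokaryote_marker": q.n_prokaryote_marker,
            }
            for q in qc
        ]
    )


def write_qc_report(qc: Sequence[SampleQC], tsv_path, json_path=None) -> None:
    table = qc_table(qc)
    table.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(table.to_dict(orient="records"), fh, indent=1, sort_keys=True)


def read_sam_alignments(path, references: Mapping[str, str]) -> list[AlignmentRecord]:
    """Import ungapped single-end alignments from a SAM file.

    Only records with a single-``M`` CIGAR are accepted (the internal
    convention — synthetic and aDNA reads are mapped ungapped). Mismatches
    are recovered by comparing the stored query to the supplied reference
    sequences; minus-strand records are re-oriented so mismatch positions
    count from the original read's 5' end.
    """
    import pysam

    out: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            cig = rec.cigartuples
            if cig is None or len(cig) != 1 or cig[0][0] != 0:
                raise ValueError(
                    f"read {rec.query_name}: only ungapped (single-M CIGAR) "
                    f"alignments are supported"
                )
            rid = rec.reference_name
            if rid not in references:
                raise KeyError(f"reference {rid!r} not provided")
            L = cig[0][1]
            start = rec.reference_start
            refseg = references[rid][start : start + L].upper()
            stored = rec.query_sequence.upper()  # aligned orientation
            strand = "-" if rec.is_reverse else "+"
            if strand == "-":
                read_seq = revcomp(stored)
                oriented_ref = revcomp(refseg)
            else:
                read_seq = stored
                oriented_ref = refseg
            mismatches = tuple(
                (i + 1, rb, qb)
                for i, (rb, qb) in enumerate(zip(oriented_ref, read_seq))
                if rb != qb
            )
            out.append(AlignmentRecord(rec.query_name, rid, start, strand, L, mismatches))
    return out
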