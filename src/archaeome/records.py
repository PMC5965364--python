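"""Shared record types: sequenced reads and ungapped alignments."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class ReadRecord:
    """A single-end sequenced fragment.

    ``qualities`` holds Phred scores encoded Sanger-style (Phred+33), one
    character per base.
    """

    read_id: str
    sequence: str
    qualities: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def phred(self) -> list[int]:
        return [ord(q) - 33 for q in self.qualities]


@dataclass
class AlignmentRecord:
    """Ungapped placement of a read on a reference.

    ``ref_start`` is 0-based on the forward reference strand. ``mismatches``
    are tuples ``(read_pos, ref_base, read_base)`` with ``read_pos`` 1-based
    from the read's 5' end and both bases given in read orientation (i.e. for
    minus-strand alignments the reference segment is reverse-complemented
    first). This is the convention misincorporation profiles are tallied in.
    """

    read_id: str
    reference_id: str
    ref_start: int
    strand: str
    read_length: int
    mismatches: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.ref_start < 0:
            raise ValueError("ref_start must be non-negative")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        for pos, _, _ in self.mismatches:
            if not 1 <= pos <= self.read_length:
                raise ValueError(
                    f"mismatch position {pos} outside read of length {self.read_length}"
                )

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatches)
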