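"""Low-level nucleotide-sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")

# ASCII codes used throughout for vectorized base comparisons
A, C, G, T = ord("A"), ord("C"), ord("G"), ord("T")

# base -> 2-bit code; 255 marks non-ACGT
CODE = np.full(256, 255, dtype=np.uint8)
for _b, _c in zip(b"ACGT", range(4)):
    CODE[_b] = _c
    CODE[ord(chr(_b).lower())] = _c

_TRANSITIONS = {(A, G), (G, A), (C, T), (T, C)}


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def revcomp_bytes(seq: bytes) -> bytes:
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_u8(seq: str) -> np.ndarray:
    """View a sequence as an array of ASCII codes (no copy of the string)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def u8_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def random_sequence(length: int, rng: np.random.Generator) -> str:
    """I.i.d. uniform ACGT sequence."""
    return u8_to_seq(np.frombuffer(b"ACGT", dtype=np.uint8)[rng.integers(0, 4, length)])


def is_transversion(ref: int | str, alt: int | str) -> bool:
    """True when a ref→alt substitution is a purine↔pyrimidine change."""
    r = ord(ref) if isinstance(ref, str) else ref
    a = ord(alt) if isinstance(alt, str) else alt
    return r != a and (r, a) not in _TRANSITIONS
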