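"""Small nucleotide-sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

# IUPAC nucleotide codes -> set of concrete bases they stand for.
IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"G", "C"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN-acgtryswkmbdhvn",
    "TGCAYRSWMKVHDBN-tgcayrswmkvhdbn",
)

AMBIGUOUS = frozenset(IUPAC) - {"A", "C", "G", "T"}

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_DECODE = np.array(list("ACGT"))


def is_iupac(seq: str) -> bool:
    return all(c.upper() in IUPAC for c in seq)


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_eq(primer_char: str, base: str) -> bool:
    """True if a read base is compatible with an IUPAC primer character."""
    return base.upper() in IUPAC.get(primer_char.upper(), set())


def hamming_iupac(primer: str, segment: str) -> int:
    """Mismatches between a primer and an equal-length read segment."""
    if len(primer) != len(segment):
        raise ValueError("primer/segment length mismatch")
    return sum(0 if iupac_eq(p, b) else 1 for p, b in zip(primer, segment))


def encode(seq: str) -> np.ndarray:
    """Encode ACGT as 0..3; anything else (ambiguity, gap) as 4."""
    return np.fromiter((_CODE.get(c, 4) for c in seq.upper()), dtype=np.uint8,
                       count=len(seq))


def decode(codes: np.ndarray) -> str:
    return "".join(_DECODE[codes])
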