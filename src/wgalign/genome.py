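"""Genome records, FASTA I/O and nucleotide encoding.

Coordinates throughout the package are 1-based and inclusive on both ends
unless a function explicitly says otherwise (MAF output is 0-based, as the
format requires).

Internally sequences are encoded over small integer codes so that the
FM-index and the dynamic-programming kernels can work on flat numpy arrays:

====  =======  =========================================================
code  symbol   role
====  =======  =========================================================
0     (term)   unique final terminator; sorts below everything
1-4   A C G T  the four nucleotides
5     (sep)    record/strand separator; never matches a pattern symbol
6     N        ambiguous base; never matches anything, including itself
====  =======  =========================================================

The final terminator is unique in the indexed text, so the lexicographic
suffix order equals the cyclic-rotation order and the BWT's LF mapping
reconstructs the text exactly.  Separators inside the text only need to be
unmatchable to keep seeds from spanning junctions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO

TERM_CODE = 0
SEP_CODE = 5
N_CODE = 6
VALID_RESIDUES = frozenset("ACGTN")

_CODE_OF = {"A": 1, "C": 2, "G": 3, "T": 4, "N": N_CODE}
_CHAR_OF = {1: "A", 2: "C", 3: "G", 4: "T", N_CODE: "N", SEP_CODE: "|", TERM_CODE: "$"}
_COMP_TABLE = str.maketrans("ACGTN", "TGCAN")

# byte-level lookup tables for fast encode/complement
_ENCODE_LUT = np.zeros(256, dtype=np.uint8)
for _ch, _code in _CODE_OF.items():
    _ENCODE_LUT[ord(_ch)] = _code
    _ENCODE_LUT[ord(_ch.lower())] = _code

_COMP_CODE_LUT = np.array([TERM_CODE, 4, 3, 2, 1, SEP_CODE, N_CODE, 0], dtype=np.uint8)

_DECODE_LUT = np.zeros(8, dtype=np.uint8)
for _code, _ch in _CHAR_OF.items():
    _DECODE_LUT[_code] = ord(_ch)


class InvalidSequenceError(ValueError):
    """Raised for empty sequences or symbols outside {A,C,G,T,N}."""


@dataclass
class Genome:
    """A single named nucleotide sequence (one FASTA record)."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def length(self) -> int:
        return len(self.seq)

    def validate(self) -> None:
        if len(self.seq) == 0:
            raise InvalidSequenceError(f"record {self.name!r}: empty sequence")
        bad = set(self.seq) - VALID_RESIDUES
        if bad:
            raise InvalidSequenceError(
                f"record {self.name!r}: invalid symbols {sorted(bad)!r}"
            )

    def fragment(self, start: int, end: int) -> str:
        """Residues between 1-based inclusive ``start`` and ``end``."""
        return self.seq[start - 1 : end]


def revcomp(seq: str) -> str:
    return seq.translate(_COMP_TABLE)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode residues to the integer alphabet (uint8)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE_LUT[raw]


def encode_complement(seq: str) -> np.ndarray:
    """Per-position complement codes (not reversed)."""
    return _COMP_CODE_LUT[encode(seq)]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP_CODE_LUT[codes][::-1]


def decode(codes: np.ndarray) -> str:
    return _DECODE_LUT[codes].tobytes().decode("ascii")


def read_fasta(path) -> list[Genome]:
    """Read a (multi-)FASTA file into validated records.

    Wrapped lines and multiple records are fine; lowercase (soft-masked)
    residues are uppercased and treated like any other residue.
    """
    genomes = []
    for rec in SeqIO.parse(str(path), "fasta"):
        g = Genome(rec.id, str(rec.seq))
        g.validate()
        genomes.append(g)
    if not genomes:
        raise InvalidSequenceError(f"{path}: no FASTA records found")
    return genomes


def write_fasta(genomes: list[Genome], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.name}\n")
            for i in range(0, len(g.seq), width):
                fh.write(g.seq[i : i + width] + "\n")
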