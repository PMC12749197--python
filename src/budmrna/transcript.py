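"""Transcript container and coordinate frames.

A transcript is a nucleotide sequence together with 1-based CDS bounds
(``cds_start`` points at the A of the start ATG, ``cds_end`` at the last base
of the stop codon).  Motif hits are reported both in absolute transcript
coordinates and in the CDS-relative frame in which +1 is the A of ATG, the
convention used throughout yeast zipcode literature.
"""

from __future__ import annotations

from dataclasses import dataclass

DNA_ALPHABET = set("ACGTUN")

_COMPLEMENT = str.maketrans("ACGU", "UGCA")

#: standard nuclear genetic code on RNA codons
GENETIC_CODE = {
    "UUU": "F", "UUC": "F", "UUA": "L", "UUG": "L",
    "CUU": "L", "CUC": "L", "CUA": "L", "CUG": "L",
    "AUU": "I", "AUC": "I", "AUA": "I", "AUG": "M",
    "GUU": "V", "GUC": "V", "GUA": "V", "GUG": "V",
    "UCU": "S", "UCC": "S", "UCA": "S", "UCG": "S",
    "CCU": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACU": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCU": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "UAU": "Y", "UAC": "Y", "UAA": "*", "UAG": "*",
    "CAU": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAU": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAU": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "UGU": "C", "UGC": "C", "UGA": "*", "UGG": "W",
    "CGU": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGU": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGU": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def as_rna(seq: str) -> str:
    """Upper-case and convert T to U."""
    return seq.upper().replace("T", "U")


def reverse_complement(seq: str) -> str:
    return as_rna(seq).translate(_COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    """Translate an RNA/DNA CDS (length divisible by 3) to protein."""
    rna = as_rna(cds)
    if len(rna) % 3:
        raise ValueError(f"CDS length {len(rna)} not divisible by 3")
    return "".join(GENETIC_CODE.get(rna[i : i + 3], "X") for i in range(0, len(rna), 3))


@dataclass(frozen=True)
class Transcript:
    """A sequence with annotated CDS bounds (1-based, inclusive)."""

    id: str
    seq: str
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        bad = set(self.seq.upper()) - DNA_ALPHABET
        if bad:
            raise ValueError(f"transcript {self.id}: non-alphabet characters {sorted(bad)}")
        if not (1 <= self.cds_start < self.cds_end <= len(self.seq)):
            raise ValueError(
                f"transcript {self.id}: CDS bounds {self.cds_start}..{self.cds_end} "
                f"outside sequence of length {len(self.seq)}"
            )
        if (self.cds_end - self.cds_start + 1) % 3:
            raise ValueError(f"transcript {self.id}: CDS length not divisible by 3")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def rna(self) -> str:
        return as_rna(self.seq)

    @property
    def cds(self) -> str:
        return self.rna[self.cds_start - 1 : self.cds_end]

    @property
    def protein(self) -> str:
        return translate(self.cds)

    def to_cds_coords(self, pos: int) -> int:
        """Absolute 1-based position -> CDS-relative (+1 = A of ATG).

        Positions 5' of the CDS map to negative values (-1 is the base just
        before the A of ATG, there is no 0); positions 3' of the stop keep
        counting past the CDS end.
        """
        rel = pos - self.cds_start + 1
        return rel if rel >= 1 else rel - 1

    def from_cds_coords(self, rel: int) -> int:
        if rel == 0:
            raise ValueError("CDS-relative coordinate 0 does not exist")
        if rel < 0:
            rel += 1
        return rel + self.cds_start - 1

    def in_cds(self, start: int, end: int) -> bool:
        """Whether the absolute interval [start, end] lies inside the CDS."""
        return self.cds_start <= start and end <= self.cds_end
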