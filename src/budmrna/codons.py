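"""Codon usage scoring for synonymous mutagenesis.

The bundled reference table holds *S. cerevisiae* genomic codon usage in
occurrences per thousand codons (standard published reference values).  The
score used throughout the package is the mean relative adaptiveness over
codons: each codon contributes w = f(codon) / max f over its synonyms, the
same per-codon weight that underlies the codon adaptation index.
"""

from __future__ import annotations

import warnings

from .transcript import GENETIC_CODE, as_rna

#: S. cerevisiae codon usage, occurrences per 1000 codons (RNA codons).
YEAST_CODON_USAGE = {
    "UUU": 26.1, "UUC": 18.4, "UUA": 26.2, "UUG": 27.2,
    "CUU": 12.3, "CUC": 5.4, "CUA": 13.4, "CUG": 10.5,
    "AUU": 30.1, "AUC": 17.2, "AUA": 17.8, "AUG": 20.9,
    "GUU": 22.1, "GUC": 11.8, "GUA": 11.8, "GUG": 10.8,
    "UCU": 23.5, "UCC": 14.2, "UCA": 18.7, "UCG": 8.6,
    "CCU": 13.5, "CCC": 6.8, "CCA": 18.3, "CCG": 5.3,
    "ACU": 20.3, "ACC": 12.7, "ACA": 17.8, "ACG": 8.0,
    "GCU": 21.2, "GCC": 12.6, "GCA": 16.2, "GCG": 6.2,
    "UAU": 18.8, "UAC": 14.8, "UAA": 1.1, "UAG": 0.5,
    "CAU": 13.6, "CAC": 7.8, "CAA": 27.3, "CAG": 12.1,
    "AAU": 35.7, "AAC": 24.8, "AAA": 41.9, "AAG": 30.8,
    "GAU": 37.6, "GAC": 20.2, "GAA": 45.6, "GAG": 19.2,
    "UGU": 8.1, "UGC": 4.8, "UGA": 0.7, "UGG": 10.4,
    "CGU": 6.4, "CGC": 2.6, "CGA": 3.0, "CGG": 1.7,
    "AGU": 14.2, "AGC": 9.8, "AGA": 21.3, "AGG": 9.2,
    "GGU": 23.9, "GGC": 9.8, "GGA": 10.9, "GGG": 6.0,
}

#: amino acid -> list of synonymous RNA codons
SYNONYMS: dict[str, list[str]] = {}
for _codon, _aa in GENETIC_CODE.items():
    SYNONYMS.setdefault(_aa, []).append(_codon)


def relative_adaptiveness(table: dict[str, float] | None = None) -> dict[str, float]:
    """Per-codon weight w = f / max f over synonymous codons, in [0, 1]."""
    table = YEAST_CODON_USAGE if table is None else table
    w = {}
    for aa, codons in SYNONYMS.items():
        present = [c for c in codons if c in table]
        if not present:
            continue
        peak = max(table[c] for c in present)
        for c in present:
            w[c] = table[c] / peak if peak > 0 else 0.0
    return w


def codon_usage_frequency(cds: str, reference_table: dict[str, float] | None = None) -> float:
    """Mean relative adaptiveness of a CDS.

    Internal stop codons are excluded from the mean with a warning; a
    terminal stop codon is excluded silently.
    """
    rna = as_rna(cds)
    if len(rna) % 3:
        raise ValueError("CDS length not divisible by 3")
    if not rna:
        raise ValueError("empty CDS")
    w = relative_adaptiveness(reference_table)
    scores = []
    n_codons = len(rna) // 3
    n_internal_stops = 0
    for k in range(n_codons):
        codon = rna[3 * k : 3 * k + 3]
        if GENETIC_CODE.get(codon) == "*":
            if k < n_codons - 1:
                n_internal_stops += 1
            continue
        if codon in w:
            scores.append(w[codon])
    if n_internal_stops:
        warnings.warn(f"{n_internal_stops} internal stop codon(s) excluded from usage mean")
    if not scores:
        raise ValueError("no scoreable codons in CDS")
    return float(sum(scores) / len(scores))
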