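"""Genetic-code tables and small sequence utilities shared across the package."""

from __future__ import annotations

from Bio.Data.CodonTable import unambiguous_dna_by_id

_TABLE = unambiguous_dna_by_id[1]

#: codon (DNA alphabet) -> one-letter amino acid, 61 sense codons
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
STOP_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.stop_codons))
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))
AMINO_ACIDS: tuple[str, ...] = tuple(sorted(set(CODON_TO_AA.values())))

_DNA_COMP = str.maketrans("ACGTN", "TGCAN")
_RNA_COMP = str.maketrans("ACGUN", "UGCAN")


def revcomp_dna(seq: str) -> str:
    return seq.translate(_DNA_COMP)[::-1]


def revcomp_rna(seq: str) -> str:
    return seq.translate(_RNA_COMP)[::-1]


def dna_to_rna(seq: str) -> str:
    return seq.replace("T", "U")


def rna_to_dna(seq: str) -> str:
    return seq.replace("U", "T")


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a DNA codon; '*' for stop, 'X' otherwise."""
    if codon in CODON_TO_AA:
        return CODON_TO_AA[codon]
    if codon in STOP_CODONS:
        return "*"
    return "X"
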