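"""Shared nucleotide/peptide helpers built on Biopython's standard genetic code."""

from __future__ import annotations

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
STOP_CODONS = tuple(standard_dna_table.stop_codons)

# Codons enumerated in the classical T/C/A/G table order, so that the "first"
# codon of each residue is the one a printed genetic-code table lists first
# (e.g. Ala -> GCT, Ser -> TCT, Arg -> CGT).
_TCAG = "TCAG"
_CODONS_TCAG = [a + b + c for a in _TCAG for b in _TCAG for c in _TCAG]

CODONS_BY_AA: dict[str, tuple[str, ...]] = {}
for _codon in _CODONS_TCAG:
    _aa = standard_dna_table.forward_table.get(_codon)
    if _aa is not None:
        CODONS_BY_AA.setdefault(_aa, [])  # type: ignore[arg-type]
        CODONS_BY_AA[_aa] = tuple(list(CODONS_BY_AA[_aa]) + [_codon])

# NNK degenerate codons (third base G or T) cover all 20 residues plus amber.
NNK_CODONS_BY_AA: dict[str, tuple[str, ...]] = {
    aa: tuple(c for c in codons if c[2] in "GT") for aa, codons in CODONS_BY_AA.items()
}


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return str(Seq(seq).reverse_complement())


def translate(seq: str) -> str:
    """Translate a DNA string in frame 0 with the standard genetic code.

    Stop codons appear as ``*``; codons containing ``N`` appear as ``X``.
    """
    return str(Seq(seq).translate())


def is_valid_peptide(peptide: str) -> bool:
    return len(peptide) > 0 and all(aa in AMINO_ACIDS for aa in peptide)
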