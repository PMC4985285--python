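"""Amino-acid and codon constants shared across the package.

All sequence work uses the standard genetic code (NCBI table 1).  A single
preferred *E. coli* trinucleotide per residue is provided so that positional
amino-acid distributions can be realized exactly at the DNA level, which is
the whole point of whole-codon (trinucleotide) synthesis as opposed to
degenerate NNK/NNN randomization.
"""

from __future__ import annotations

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

#: The 20 canonical amino acids, one-letter codes, alphabetical.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Stop trinucleotides of the standard code.
STOP_CODONS: frozenset[str] = frozenset(standard_dna_table.stop_codons)

#: codon -> amino acid for all 61 sense codons.
CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)

#: One high-usage *E. coli* codon per residue (exact-realization default).
PREFERRED_CODON: dict[str, str] = {
    "A": "GCG", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGC", "H": "CAC", "I": "ATC", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCG", "Q": "CAG", "R": "CGT",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAT",
}

#: Residues treated as strongly hydrophobic when capping aggregation risk.
HYDROPHOBIC_RESIDUES: frozenset[str] = frozenset("FILMVW")


def translate(dna: str) -> str:
    """Translate ``dna`` in frame 1 (internal stops rendered as ``*``).

    Trailing bases that do not complete a codon are ignored.
    """
    usable = len(dna) - len(dna) % 3
    return str(Seq(dna[:usable]).translate())


def reverse_complement(dna: str) -> str:
    """Return the reverse complement of a DNA string."""
    return str(Seq(dna).reverse_complement())


def reverse_translate(protein: str) -> str:
    """Back-translate a protein using the preferred single-codon table."""
    try:
        return "".join(PREFERRED_CODON[aa] for aa in protein)
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"cannot back-translate residue {exc}") from exc
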