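"""Codon-level effect classification of single-nucleotide substitutions.

Shared by the variant annotator and by the simulator (which must verify that a
planted substitution realizes its intended effect class). Uses the bacterial
genetic code (NCBI translation table 11).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data import CodonTable

from .seqs import revcomp

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]

SYNONYMOUS = "synonymous"
NON_SYNONYMOUS = "non-synonymous"
NONSENSE = "nonsense"
INTERGENIC = "intergenic"

EFFECT_CLASSES = (SYNONYMOUS, NON_SYNONYMOUS, NONSENSE, INTERGENIC)


def translate_codon(codon: str) -> str:
    """Single-letter amino acid for a codon; 'X' denotes a stop."""
    codon = codon.upper()
    if codon in _TABLE11.stop_codons:
        return "X"
    return _TABLE11.forward_table[codon]


@dataclass(frozen=True)
class Effect:
    mut_type: str
    protein_change: str  # e.g. "R61C", "Q808X"; empty for intergenic
    gene_id: str  # empty for intergenic


def classify_in_gene(
    gene_seq_fwd: str, gene_start: int, gene_end: int, strand: str,
    pos: int, ref: str, alt: str,
) -> Effect:
    """Classify a substitution at reference position ``pos`` inside one CDS.

    ``gene_seq_fwd`` is the reference-strand slice [gene_start, gene_end]
    (1-based inclusive). The coding sequence is that slice for '+' genes and
    its reverse complement for '-' genes.
    """
    length = gene_end - gene_start + 1
    if length % 3 != 0:
        raise ValueError(f"CDS length {length} is not a multiple of 3")
    if not (gene_start <= pos <= gene_end):
        raise ValueError("position outside gene")
    if strand == "+":
        offset = pos - gene_start
        cds_ref, cds_alt = ref, alt
    else:
        offset = gene_end - pos
        cds_ref, cds_alt = revcomp(ref), revcomp(alt)
    codon_idx = offset // 3
    within = offset % 3
    cds_start = codon_idx * 3
    if strand == "+":
        codon = gene_seq_fwd[cds_start : cds_start + 3]
    else:
        codon = revcomp(gene_seq_fwd)[cds_start : cds_start + 3]
    if codon[within] != cds_ref:
        raise ValueError(
            f"reference base mismatch in codon: expected {cds_ref}, "
            f"codon {codon} position {within}"
        )
    mutated = codon[:within] + cds_alt + codon[within + 1 :]
    aa_ref = translate_codon(codon)
    aa_alt = translate_codon(mutated)
    change = f"{aa_ref}{codon_idx + 1}{aa_alt}"
    if aa_alt == "X" and aa_ref != "X":
        mut_type = NONSENSE
    elif aa_ref == aa_alt:
        mut_type = SYNONYMOUS
    else:
        mut_type = NON_SYNONYMOUS
    return Effect(mut_type, change, "")
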