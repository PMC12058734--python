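"""Shared residue-level reference tables.

Houses the Chou–Fasman beta-sheet propensity scale, the hydrophobic residue
set used for composition screening, and a ranked *E. coli* K-12 codon-usage
table for reverse translation.  All tables are plain dicts so callers can
supply drop-in replacements loaded from file.
"""

from __future__ import annotations

CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: Chou–Fasman conformational parameters P(beta) — the classical strand
#: propensity scale.  Values > 1 favour strand.
CHOU_FASMAN_BETA = {
    "A": 0.83, "R": 0.93, "N": 0.89, "D": 0.54, "C": 1.19,
    "Q": 1.10, "E": 0.37, "G": 0.75, "H": 0.87, "I": 1.60,
    "K": 0.74, "L": 1.30, "M": 1.05, "F": 1.38, "P": 0.55,
    "S": 0.75, "T": 1.19, "W": 1.37, "Y": 1.47, "V": 1.70,
}

#: Conventional hydrophobic core set (Kyte–Doolittle-positive residues).
HYDROPHOBIC_SET = frozenset("AVLIMFWC")

#: Codons ranked most-frequent-first for highly expressed E. coli K-12 genes.
#: '*' is the stop "residue" appended by the reverse translator.
ECOLI_CODON_RANKS = {
    "A": ["GCG", "GCC", "GCA", "GCT"],
    "R": ["CGT", "CGC", "CGG", "CGA", "AGA", "AGG"],
    "N": ["AAC", "AAT"],
    "D": ["GAT", "GAC"],
    "C": ["TGC", "TGT"],
    "Q": ["CAG", "CAA"],
    "E": ["GAA", "GAG"],
    "G": ["GGC", "GGT", "GGG", "GGA"],
    "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"],
    "L": ["CTG", "TTA", "TTG", "CTT", "CTC", "CTA"],
    "K": ["AAA", "AAG"],
    "M": ["ATG"],
    "F": ["TTT", "TTC"],
    "P": ["CCG", "CCA", "CCT", "CCC"],
    "S": ["AGC", "TCT", "TCC", "TCG", "AGT", "TCA"],
    "T": ["ACC", "ACA", "ACG", "ACT"],
    "W": ["TGG"],
    "Y": ["TAT", "TAC"],
    "V": ["GTG", "GTT", "GTC", "GTA"],
    "*": ["TAA", "TGA", "TAG"],
}
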