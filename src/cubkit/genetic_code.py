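"""Standard genetic code tables shared across the package.

All codon bookkeeping (synonymous families, degeneracy classes, the 59-codon
order used for RSCU matrices) lives here so that every module agrees on it.
"""

from __future__ import annotations

from Bio.Data import CodonTable as _CodonTable

BASES: str = "ACGT"

_std = _CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, sense codons only (61 entries)
CODON_TO_AA: dict[str, str] = dict(_std.forward_table)

STOP_CODONS: tuple[str, ...] = tuple(sorted(_std.stop_codons))  # TAA, TAG, TGA

#: the 61 sense codons in fixed alphabetical order
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

#: amino acid -> alphabetically sorted synonymous codons
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon in SENSE_CODONS:
    AA_TO_CODONS.setdefault(CODON_TO_AA[_codon], ())
AA_TO_CODONS = {
    aa: tuple(c for c in SENSE_CODONS if CODON_TO_AA[c] == aa) for aa in AA_TO_CODONS
}

#: amino acid -> number of synonymous codons
DEGENERACY: dict[str, int] = {aa: len(cs) for aa, cs in AA_TO_CODONS.items()}

#: amino acids with at least two synonymous codons (18 of them)
MULTI_CODON_AAS: tuple[str, ...] = tuple(
    sorted(aa for aa, k in DEGENERACY.items() if k >= 2)
)

#: the 59 codons entering RSCU / PCA (sense codons minus ATG and TGG),
#: fixed alphabetical column order for every matrix written by this package
RSCU_CODONS: tuple[str, ...] = tuple(c for c in SENSE_CODONS if c not in ("ATG", "TGG"))

#: degeneracy class -> amino acids (Wright's ENc classes; 6-fold kept whole)
ENC_CLASSES: dict[int, tuple[str, ...]] = {
    k: tuple(sorted(aa for aa, d in DEGENERACY.items() if d == k))
    for k in (2, 3, 4, 6)
}

# the eight four-codon sets entering the PR2 plot: Ala, Gly, Pro, Thr, Val
# plus the CG (Arg), CT (Leu) and TC (Ser) quartets
PR2_QUARTET_PREFIXES: tuple[str, ...] = ("AC", "CC", "CG", "CT", "GC", "GG", "GT", "TC")
PR2_CODONS: tuple[str, ...] = tuple(
    p + b for p in PR2_QUARTET_PREFIXES for b in BASES
)

DINUCLEOTIDES: tuple[str, ...] = tuple(x + y for x in BASES for y in BASES)


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a sense codon; '*' for a stop codon."""
    if codon in STOP_CODONS:
        return "*"
    return CODON_TO_AA[codon]
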