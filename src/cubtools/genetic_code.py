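"""Standard genetic-code tables shared across the package.

All analyses use table-1 amino-acid assignments (bacterial CDS annotated
under table 11 differ only in permissive start codons, which are counted
as their table-1 amino acids, e.g. GTG starts count as Val).
"""

from __future__ import annotations

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"

_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: The three stop codons of the standard code.
STOP_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.stop_codons))

#: codon -> one-letter amino acid, for the 61 sense codons.
CODON_TO_AA: dict[str, str] = dict(sorted(_TABLE.forward_table.items()))

#: The 61 sense codons in alphabetical order.
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

#: All 64 codons in alphabetical order.
ALL_CODONS: tuple[str, ...] = tuple(sorted(SENSE_CODONS + STOP_CODONS))


def _families() -> dict[str, tuple[str, ...]]:
    fams: dict[str, list[str]] = {}
    for codon, aa in CODON_TO_AA.items():
        fams.setdefault(aa, []).append(codon)
    return {aa: tuple(sorted(c)) for aa, c in sorted(fams.items())}


#: amino acid -> synonymous codons, all 20 amino acids.
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = _families()

#: The 18 amino acids with >= 2 synonymous codons (Met and Trp excluded).
DEGENERATE_FAMILIES: dict[str, tuple[str, ...]] = {
    aa: codons for aa, codons in SYNONYMOUS_FAMILIES.items() if len(codons) >= 2
}

#: The 59 sense codons of degenerate families; canonical vector order for
#: RSCU vectors, CAI weights and the R(A,B)/D(A,B) similarity index.
RSCU_CODONS: tuple[str, ...] = tuple(
    c for c in SENSE_CODONS if len(SYNONYMOUS_FAMILIES[CODON_TO_AA[c]]) >= 2
)

#: degeneracy class (2/3/4/6-fold) -> amino acids in that class.
DEGENERACY_CLASSES: dict[int, tuple[str, ...]] = {}
for _aa, _codons in DEGENERATE_FAMILIES.items():
    DEGENERACY_CLASSES.setdefault(len(_codons), ())
    DEGENERACY_CLASSES[len(_codons)] += (_aa,)

AROMATIC_AAS = frozenset("FYW")

AMINO_ACIDS: tuple[str, ...] = tuple(sorted(SYNONYMOUS_FAMILIES))


def translate_codons(codons) -> str:
    """Translate an iterable of sense codons to a one-letter protein string."""
    return "".join(CODON_TO_AA[c] for c in codons)
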