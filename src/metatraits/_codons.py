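"""Synonymous-codon family tables for effective-number-of-codons statistics.

Families are derived from the standard genetic code (NCBI translation
table 1, identical to the bacterial table 11 for coding assignments):
every amino acid with two or more codons forms one synonymous family.
Met and Trp (single-codon) and the three stop codons are excluded,
leaving 59 codons in 18 families with degeneracies 2, 3, 4 and 6
(Ile is the single 3-fold family; Leu, Ser and Arg are kept as 6-fold
families rather than split by first-position nucleotide).
"""

from __future__ import annotations

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: amino acid -> tuple of synonymous codons (sorted), only families with >= 2 codons
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in _TABLE.forward_table.items():
    SYNONYMOUS_FAMILIES.setdefault(_aa, [])
    SYNONYMOUS_FAMILIES[_aa].append(_codon)
SYNONYMOUS_FAMILIES = {
    aa: tuple(sorted(codons))
    for aa, codons in SYNONYMOUS_FAMILIES.items()
    if len(codons) >= 2
}

#: degeneracy (family size) per amino-acid family
DEGENERACY: dict[str, int] = {aa: len(c) for aa, c in SYNONYMOUS_FAMILIES.items()}

#: all 59 codons participating in ENC computations, in a fixed order
SYNONYMOUS_CODONS: tuple[str, ...] = tuple(
    codon for aa in sorted(SYNONYMOUS_FAMILIES) for codon in SYNONYMOUS_FAMILIES[aa]
)

#: codon -> its amino-acid family
CODON_TO_FAMILY: dict[str, str] = {
    codon: aa for aa, codons in SYNONYMOUS_FAMILIES.items() for codon in codons
}

#: degeneracy class -> (number of families, ENC weight); weights follow
#: ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6
FAMILIES_PER_CLASS: dict[int, int] = {}
for _aa, _k in DEGENERACY.items():
    FAMILIES_PER_CLASS[_k] = FAMILIES_PER_CLASS.get(_k, 0) + 1

assert sorted(FAMILIES_PER_CLASS) == [2, 3, 4, 6]
assert FAMILIES_PER_CLASS == {2: 9, 3: 1, 4: 5, 6: 3}
assert len(SYNONYMOUS_CODONS) == 59
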