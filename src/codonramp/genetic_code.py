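"""Standard genetic code tables shared by every module.

Built once from Biopython's standard (NCBI table 1) codon table. All codons
are 3-letter upper-case DNA strings over {A, C, G, T}.
"""

from __future__ import annotations

from Bio.Data import CodonTable

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, for the 61 sense codons
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)

#: the three stop codons
STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)

#: the 61 sense codons, sorted
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

#: amino acid -> sorted tuple of synonymous codons
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon in SENSE_CODONS:
    AA_TO_CODONS.setdefault(CODON_TO_AA[_codon], ())
AA_TO_CODONS = {
    aa: tuple(c for c in SENSE_CODONS if CODON_TO_AA[c] == aa) for aa in AA_TO_CODONS
}

AMINO_ACIDS: tuple[str, ...] = tuple(sorted(AA_TO_CODONS))

#: canonical Start plus the common near-cognate alternative Start codons,
#: all unusually fast and depleted in 5' leader regions
START_LIKE_CODONS: frozenset[str] = frozenset({"ATG", "ATT", "TTG", "ATA"})


def normalize_codon(codon: str) -> str:
    """Upper-case a codon and map RNA U to DNA T."""
    return codon.strip().upper().replace("U", "T")


def translate_codons(codons) -> str:
    """Translate a sense-codon iterable into a one-letter protein string."""
    return "".join(CODON_TO_AA[c] for c in codons)
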