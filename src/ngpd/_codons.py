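"""Standard genetic code tables shared by the library simulator and the read processor."""

from Bio.Data import CodonTable

_STANDARD = CodonTable.unambiguous_dna_by_name["Standard"]

#: codon (DNA, upper case) -> one-letter amino acid; stop codons map to '*'
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    CODON_TO_AA[_stop] = "*"

#: amino acid -> sorted tuple of synonymous codons
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon in sorted(_STANDARD.forward_table):
    AA_TO_CODONS.setdefault(_STANDARD.forward_table[_codon], []).append(_codon)  # type: ignore[arg-type]
AA_TO_CODONS = {aa: tuple(codons) for aa, codons in AA_TO_CODONS.items()}

#: the 20 standard residues in alphabetical one-letter order
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def translate_codon(codon: str) -> str:
    """Translate one DNA codon; codons containing N (or any non-ACGT base) give 'X'."""
    return CODON_TO_AA.get(codon, "X")
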