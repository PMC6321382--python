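"""Residue alphabet shared by every module.

The 20 standard amino acids in alphabetical one-letter order, plus the
pseudo-residue 'X' used both for terminal padding of peptide windows and
for unknown residues in input sequences.
"""

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
PAD: str = "X"
ALPHABET: str = AMINO_ACIDS + PAD

AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS)}
ALPHABET_INDEX: dict[str, int] = {a: i for i, a in enumerate(ALPHABET)}

#: the 400 ordered amino-acid pairs, first letter major: AA, AC, ..., YY
AA_PAIRS: list[str] = [a + b for a in AMINO_ACIDS for b in AMINO_ACIDS]
PAIR_INDEX: dict[str, int] = {p: i for i, p in enumerate(AA_PAIRS)}
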