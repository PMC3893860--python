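"""The 20-letter amino-acid alphabet and fixed column orderings.

All feature vectors in the toolkit use a fixed alphabetical ordering of the
one-letter residue codes so that encodings are deterministic across runs.
"""

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: ordered residue pairs AA, AC, ..., YY (400 columns)
PAIRS = tuple(a + b for a in AMINO_ACIDS for b in AMINO_ACIDS)

PAIR_INDEX = {p: i for i, p in enumerate(PAIRS)}


def is_standard(sequence: str) -> bool:
    """True iff every character is one of the 20 standard residue letters."""
    return all(c in AA_INDEX for c in sequence)
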