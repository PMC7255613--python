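"""The 20-letter amino-acid alphabet and index maps used throughout the package."""

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

GAP = "-"
UNKNOWN = "X"

N_AA = 20


def is_standard_aa(residue: str) -> bool:
    return residue in AA_INDEX
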