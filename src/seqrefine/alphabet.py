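"""Canonical amino-acid alphabet and token encoding.

The canonical order is alphabetical by one-letter code. All probability
profiles, substitution matrices and model outputs are indexed in this order.
Token index 20 is the distinguished *unknown* symbol ``X`` used for masked
positions in partial sequences.
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
UNKNOWN: str = "X"
ALPHABET: str = AMINO_ACIDS + UNKNOWN

N_AMINO_ACIDS: int = 20
N_TOKENS: int = 21
UNKNOWN_INDEX: int = 20

AA_TO_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(ALPHABET)}

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}

# Common non-standard residues mapped to their 20-letter parent type.
NONSTANDARD_PARENT: dict[str, str] = {
    "MSE": "M",  # selenomethionine
    "SEC": "C",  # selenocysteine
    "PYL": "K",  # pyrrolysine
    "CSO": "C",  # S-hydroxycysteine
    "SEP": "S",  # phosphoserine
    "TPO": "T",  # phosphothreonine
    "PTR": "Y",  # phosphotyrosine
    "MLY": "K",  # N-dimethyl-lysine
    "HYP": "P",  # 4-hydroxyproline
}


def encode_sequence(seq: str, allow_unknown: bool = True) -> np.ndarray:
    """Encode a one-letter sequence into integer tokens (int64).

    Lowercase input is accepted and upper-cased. Raises ``ValueError`` on
    characters outside the alphabet (or on ``X`` when ``allow_unknown`` is
    False).
    """
    seq = seq.upper()
    tokens = np.empty(len(seq), dtype=np.int64)
    for i, ch in enumerate(seq):
        if ch not in AA_TO_INDEX:
            raise ValueError(f"invalid sequence character {ch!r} at position {i}")
        idx = AA_TO_INDEX[ch]
        if idx == UNKNOWN_INDEX and not allow_unknown:
            raise ValueError(f"unknown residue symbol 'X' not allowed at position {i}")
        tokens[i] = idx
    return tokens


def decode_sequence(tokens: np.ndarray) -> str:
    """Decode integer tokens back into a one-letter string."""
    return "".join(ALPHABET[int(t)] for t in tokens)
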