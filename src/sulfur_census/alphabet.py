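"""Protein alphabet, background amino-acid frequencies, and integer encoding.

The 20 canonical residues are indexed in the fixed order of ``AMINO_ACIDS``;
``X`` is the ambiguity symbol and scores as background everywhere. The
background distribution is the Robinson & Robinson amino-acid frequency set,
the conventional null model for profile scoring.
"""

from __future__ import annotations

import numpy as np

from .errors import AlphabetError, EmptyInputError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUITY = "X"
GAP_CHARS = frozenset("-.")

AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
AMBIG_INDEX = 20
PAD_INDEX = 21

# Robinson & Robinson (1991) frequencies, reordered to AMINO_ACIDS.
_RR = {
    "A": 0.078047, "C": 0.019246, "D": 0.053640, "E": 0.062949,
    "F": 0.038556, "G": 0.073772, "H": 0.021992, "I": 0.051420,
    "K": 0.057438, "L": 0.090191, "M": 0.022425, "N": 0.044873,
    "P": 0.052028, "Q": 0.042644, "R": 0.051295, "S": 0.071198,
    "T": 0.058413, "V": 0.064409, "W": 0.013298, "Y": 0.032165,
}

BACKGROUND = np.array([_RR[aa] for aa in AMINO_ACIDS], dtype=float)
BACKGROUND /= BACKGROUND.sum()


def encode(sequence: str) -> np.ndarray:
    """Encode a protein sequence to integer indices (``X`` -> 20).

    Raises
    ------
    EmptyInputError
        If the sequence is empty.
    AlphabetError
        If a symbol is neither a canonical residue nor the ambiguity symbol.
    """
    if not sequence:
        raise EmptyInputError("empty protein sequence")
    out = np.empty(len(sequence), dtype=np.int64)
    for i, ch in enumerate(sequence.upper()):
        if ch in AA_INDEX:
            out[i] = AA_INDEX[ch]
        elif ch == AMBIGUITY:
            out[i] = AMBIG_INDEX
        else:
            raise AlphabetError(f"symbol {ch!r} at position {i} is not a protein residue")
    return out


def degap(sequence: str) -> str:
    """Remove gap characters from an aligned sequence."""
    return "".join(ch for ch in sequence if ch not in GAP_CHARS)
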