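"""Amino-acid alphabet handling and substitution-matrix preparation.

Sequences are restricted to the 20 canonical residues plus ``X`` (unknown /
masked).  ``X`` is scored as a worst-case mismatch (the floor of the partner
residue's substitution row) and never counts as a match when identity is
computed, so translated pseudogene fragments cannot inflate identity.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

#: canonical residues, fixed encoding order; X is always the last code.
CANONICAL = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = CANONICAL + "X"
X_CODE = len(CANONICAL)

_CODE = {aa: i for i, aa in enumerate(ALPHABET)}

_VALID = frozenset(ALPHABET)


def is_valid_sequence(seq: str) -> bool:
    """True if every residue is one of the 20 canonical letters or X."""
    return bool(seq) and set(seq) <= _VALID


def encode(seq: str) -> np.ndarray:
    """Encode a protein string as uint8 codes for the DP kernels.

    Raises ``ValueError`` on residues outside the accepted alphabet.
    """
    try:
        return np.fromiter((_CODE[aa] for aa in seq), dtype=np.uint8, count=len(seq))
    except KeyError as exc:
        raise ValueError(f"residue {exc.args[0]!r} outside alphabet {ALPHABET}") from None


def load_matrix(name: str = "BLOSUM62") -> np.ndarray:
    """Return a (21, 21) int32 substitution matrix over :data:`ALPHABET`.

    Scores for the canonical residues come from the named matrix as shipped
    with biopython.  The X row/column is overridden with the minimum of the
    partner residue's row, making X at least as unfavourable as the worst
    mismatch.
    """
    raw = substitution_matrices.load(name)
    sub = np.zeros((21, 21), dtype=np.int32)
    for i, a in enumerate(CANONICAL):
        for j, b in enumerate(CANONICAL):
            sub[i, j] = int(raw[a][b])
    row_min = sub[:20, :20].min(axis=1)
    sub[:20, X_CODE] = row_min
    sub[X_CODE, :20] = row_min
    sub[X_CODE, X_CODE] = row_min.min()
    return sub
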