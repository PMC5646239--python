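"""Protein substitution scoring for the translated screen.

The scoring alphabet is the 20 amino acids plus ``X`` (unknown, from codons
containing N) and ``*`` (stop, from translating through read-through frames).
Scores come from BLOSUM62 with two policy overrides chosen so degraded
endogenous loci remain alignable: ``X`` scores 0 against everything, and
``*`` scores −4 against everything (``*`` takes precedence over ``X``).
Alignments are never split at stops; stop codons are counted downstream as
integrity evidence instead.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

AA20 = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AA20 + "X*"
STOP_SCORE = -4
X_SCORE = 0

# default search parameters (tBLASTn-like; config-exposed throughout)
DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1
DEFAULT_MIN_SCORE = 60
DEFAULT_MAX_GAP_NT = 1000
DEFAULT_MARGIN_MIN = 30

_ENCODER = np.full(256, -1, dtype=np.int8)
for _i, _ch in enumerate(ALPHABET):
    _ENCODER[ord(_ch)] = _i


def blosum62_extended() -> np.ndarray:
    """22x22 integer matrix over ``ALPHABET`` with the X/* overrides applied."""
    src = substitution_matrices.load("BLOSUM62")
    n = len(ALPHABET)
    mat = np.zeros((n, n), dtype=np.int32)
    for i, a in enumerate(AA20):
        for j, b in enumerate(AA20):
            mat[i, j] = int(src[a, b])
    xi = ALPHABET.index("X")
    mat[xi, :] = X_SCORE
    mat[:, xi] = X_SCORE
    si = ALPHABET.index("*")
    mat[si, :] = STOP_SCORE
    mat[:, si] = STOP_SCORE
    return mat


DEFAULT_MATRIX = blosum62_extended()


def encode(seq: str) -> np.ndarray:
    """Encode a peptide over ``ALPHABET`` as uint8 indices."""
    arr = _ENCODER[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr < 0).any():
        bad = int(np.argmax(arr < 0))
        raise ValueError(f"illegal residue {seq[bad]!r} at position {bad}")
    return arr.astype(np.uint8)
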