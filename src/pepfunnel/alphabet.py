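"""The 21-letter gapped amino-acid alphabet and integer encodings.

The gap character ``-`` is a first-class symbol: every model in this package
(profiles, PSSM, RBM) treats it exactly like a residue, so q = 21.
"""

from __future__ import annotations

import numpy as np

#: Alphabet order: the 20 standard residues alphabetically, then the gap.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY-"
GAP = "-"
Q = len(ALPHABET)  # 21
GAP_INDEX = ALPHABET.index(GAP)

_CHAR_TO_INDEX = {c: i for i, c in enumerate(ALPHABET)}


class AlphabetError(ValueError):
    """A sequence contains a character outside the 21-symbol alphabet."""


def encode(sequence: str) -> np.ndarray:
    """Encode a sequence as an int8 vector of alphabet indices."""
    try:
        return np.fromiter(
            (_CHAR_TO_INDEX[c] for c in sequence), dtype=np.int8, count=len(sequence)
        )
    except KeyError as exc:
        raise AlphabetError(
            f"illegal symbol {exc.args[0]!r}; allowed: {ALPHABET!r}"
        ) from None


def decode(indices: np.ndarray) -> str:
    return "".join(ALPHABET[i] for i in np.asarray(indices, dtype=int))


def encode_many(sequences) -> np.ndarray:
    """Encode an iterable of equal-length sequences as an (n, N) int8 matrix."""
    seqs = list(sequences)
    if not seqs:
        return np.empty((0, 0), dtype=np.int8)
    n_col = len(seqs[0])
    out = np.empty((len(seqs), n_col), dtype=np.int8)
    for k, s in enumerate(seqs):
        if len(s) != n_col:
            raise ValueError(
                f"ragged input: sequence {k} has length {len(s)}, expected {n_col}"
            )
        out[k] = encode(s)
    return out


def one_hot(codes: np.ndarray) -> np.ndarray:
    """One-hot encode an (n, N) code matrix into (n, N, Q) floats."""
    codes = np.atleast_2d(codes)
    out = np.zeros(codes.shape + (Q,), dtype=np.float64)
    n_idx, i_idx = np.indices(codes.shape)
    out[n_idx, i_idx, codes] = 1.0
    return out
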