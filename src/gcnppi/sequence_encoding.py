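"""Fixed-length one-hot encoding of amino-acid sequences.

Each residue maps to a unit vector over the 20 standard amino acids
(alphabetical order A,C,D,...,Y).  A sequence of length ``n`` becomes an
``L x 20`` binary matrix: shorter sequences are zero-padded at the FRONT,
longer ones are truncated at the FRONT (the last ``L`` residues are kept),
so residue ``i`` of a short sequence always lands in row ``L - n + i``.
Non-standard letters (B, J, O, U, X, Z) encode as an all-zero row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data_io import NONSTANDARD_RESIDUES, SequenceRecord

log = logging.getLogger(__name__)

#: The 20 standard one-letter codes in frozen alphabetical order.
ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"

#: Residue letter -> column index in the one-hot matrix.
ALPHABET_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(ALPHABET)}

#: Default fixed encoding length (maximum sequence length).
DEFAULT_LENGTH: int = 850


@dataclass(frozen=True)
class OneHotMatrix:
    """An ``L x 20`` one-hot encoding of one protein sequence."""

    values: np.ndarray
    source_length: int

    @property
    def L(self) -> int:
        return self.values.shape[0]

    @property
    def encoded_residues(self) -> int:
        """Number of rows carrying a residue (``min(source_length, L)``)."""
        return min(self.source_length, self.L)


def encode_sequence(record: SequenceRecord,
                    L: int = DEFAULT_LENGTH) -> OneHotMatrix:
    """Encode a sequence record as a fixed-length one-hot matrix.

    Parameters
    ----------
    record
        The protein to encode; residues must be upper-case.
    L
        Fixed number of rows of the output matrix.
    """
    if L <= 0:
        raise ValueError(f"encoding length L must be positive, got {L}")
    residues = record.residues
    if not residues:
        raise ValueError(f"protein {record.protein_id!r} has no residues")
    n = len(residues)
    if n > L:
        residues = residues[-L:]  # keep the tail: front truncation
    m = np.zeros((L, len(ALPHABET)), dtype=np.float64)
    offset = L - len(residues)  # front padding for short sequences
    warned: set[str] = set()
    for i, aa in enumerate(residues):
        col = ALPHABET_INDEX.get(aa)
        if col is None:
            if aa in NONSTANDARD_RESIDUES and aa not in warned:
                log.warning(
                    "protein %s: non-standard residue %r encoded as zeros",
                    record.protein_id, aa,
                )
                warned.add(aa)
            continue  # all-zero row, indistinguishable from padding
        m[offset + i, col] = 1.0
    return OneHotMatrix(values=m, source_length=n)


def flatten_encoding(matrix: OneHotMatrix) -> np.ndarray:
    """Flatten an encoding row-major into a length ``L*20`` feature vector."""
    return matrix.values.reshape(-1)


def encode_dataset(records, L: int = DEFAULT_LENGTH) -> np.ndarray:
    """Stack flattened encodings of *records* into an ``N x (L*20)`` matrix."""
    return np.stack([
        flatten_encoding(encode_sequence(rec, L)) for rec in records
    ])
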