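"""Scoring schemes for local alignment.

Protein scoring uses BLOSUM62; nucleotide scoring is match/mismatch.
Affine gap convention: a gap of length L costs ``-(gap_open + (L-1) * gap_extend)``,
i.e. ``gap_open`` is the cost of the first gap column and ``gap_extend`` the cost
of each additional column.  Both penalties are stored as negative integers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

# Alphabets: index positions define the integer encoding used by the DP kernels.
PROTEIN_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
NUCLEOTIDE_ALPHABET = "ACGTN"

# IUPAC nucleotide ambiguity codes collapse onto N: they never score as a match
# and never count as an identity.
_NUC_AMBIGUITY = set("RYSWKMBDHVN")

_PROTEIN_INDEX = {c: i for i, c in enumerate(PROTEIN_ALPHABET)}
_NUC_INDEX = {c: i for i, c in enumerate(NUCLEOTIDE_ALPHABET)}


class AlphabetError(ValueError):
    """Sequence contains characters outside the scheme's alphabet."""


def _blosum62_matrix() -> np.ndarray:
    blosum = substitution_matrices.load("BLOSUM62")
    n = len(PROTEIN_ALPHABET)
    mat = np.zeros((n, n), dtype=np.int32)
    for i, a in enumerate(PROTEIN_ALPHABET):
        for j, b in enumerate(PROTEIN_ALPHABET):
            mat[i, j] = int(blosum[a][b])
    return mat


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties for one alphabet.

    Use the :meth:`protein` / :meth:`nucleotide` constructors rather than
    building instances by hand.
    """

    kind: str                      # "protein" | "nucleotide"
    matrix: np.ndarray = field(repr=False)
    alphabet: str
    gap_open: int
    gap_extend: int

    def __post_init__(self) -> None:
        if self.kind not in ("protein", "nucleotide"):
            raise ValueError(f"unknown scoring kind: {self.kind!r}")
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("gap penalties must be negative")
        if not np.array_equal(self.matrix, self.matrix.T):
            raise ValueError("substitution matrix must be symmetric")

    @classmethod
    def protein(cls, gap_open: int = -11, gap_extend: int = -1) -> "ScoringScheme":
        return cls("protein", _blosum62_matrix(), PROTEIN_ALPHABET, gap_open, gap_extend)

    @classmethod
    def nucleotide(
        cls,
        match: int = 2,
        mismatch: int = -3,
        gap_open: int = -5,
        gap_extend: int = -2,
    ) -> "ScoringScheme":
        n = len(NUCLEOTIDE_ALPHABET)
        mat = np.full((n, n), mismatch, dtype=np.int32)
        np.fill_diagonal(mat, match)
        # N scores as a mismatch against everything, including itself.
        mat[-1, :] = mismatch
        mat[:, -1] = mismatch
        return cls("nucleotide", mat, NUCLEOTIDE_ALPHABET, gap_open, gap_extend)

    def encode(self, seq: str) -> np.ndarray:
        """Map a sequence onto integer codes for the DP kernels."""
        if not seq:
            raise ValueError("empty sequence")
        s = seq.upper()
        if self.kind == "nucleotide":
            codes = np.empty(len(s), dtype=np.int8)
            for i, c in enumerate(s):
                idx = _NUC_INDEX.get(c)
                if idx is None:
                    if c in _NUC_AMBIGUITY:
                        idx = _NUC_INDEX["N"]
                    else:
                        raise AlphabetError(
                            f"character {c!r} not valid for nucleotide scoring"
                        )
                codes[i] = idx
            return codes
        codes = np.empty(len(s), dtype=np.int8)
        for i, c in enumerate(s):
            idx = _PROTEIN_INDEX.get(c)
            if idx is None:
                raise AlphabetError(f"character {c!r} not valid for protein scoring")
            codes[i] = idx
        return codes

    def identity_eligible(self) -> np.ndarray:
        """Boolean mask of alphabet positions that may count as identities.

        Ambiguity codes (N, B, Z, X) never count as identities even when the
        two symbols are equal.
        """
        if self.kind == "nucleotide":
            mask = np.ones(len(self.alphabet), dtype=np.bool_)
            mask[_NUC_INDEX["N"]] = False
            return mask
        mask = np.ones(len(self.alphabet), dtype=np.bool_)
        for c in "BZX":
            mask[_PROTEIN_INDEX[c]] = False
        return mask
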