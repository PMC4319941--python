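"""Smith-Waterman local alignment with affine gaps.

Two execution paths share one DP kernel:

* sequences whose DP table fits under ``max_full_cells`` are aligned exactly;
* larger problems (fragment-versus-genome searches) are first anchored with
  exact k-mer seeding, and the full DP is run on the banded subject window
  around the best-supported diagonal.

The kernel is numba-compiled; the pure-Python reference used by the test
suite lives with the tests so the two implementations stay independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
from numba import njit

from .scoring import ScoringScheme

_SEED_K = {"nucleotide": 11, "protein": 5}
_WINDOW_PAD = 48


@dataclass(frozen=True)
class LocalAlignment:
    """One local alignment with identity and coverage bookkeeping.

    Spans are half-open, 0-based intervals on the original sequences.
    ``identity_pct`` uses the gap-inclusive denominator (identical columns
    over all aligned columns, gaps included).
    """

    query_id: str
    subject_id: str
    score: int
    identity_pct: float
    alignment_length: int
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    query_coverage: float
    subject_coverage: float


@njit(cache=True)
def _sw_fill(a, b, matrix, gap_open, gap_extend):  # pragma: no cover - numba
    m = a.shape[0]
    n = b.shape[0]
    neg = -(1 << 30)
    H = np.zeros((m + 1, n + 1), np.int32)
    E = np.full((m + 1, n + 1), neg, np.int32)
    F = np.full((m + 1, n + 1), neg, np.int32)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        ai = a[i - 1]
        for j in range(1, n + 1):
            e = H[i, j - 1] + gap_open
            if E[i, j - 1] + gap_extend > e:
                e = E[i, j - 1] + gap_extend
            E[i, j] = e
            f = H[i - 1, j] + gap_open
            if F[i - 1, j] + gap_extend > f:
                f = F[i - 1, j] + gap_extend
            F[i, j] = f
            h = H[i - 1, j - 1] + matrix[ai, b[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    return H, E, F, best, bi, bj


@njit(cache=True)
def _sw_traceback(a, b, H, E, F, matrix, gap_open, gap_extend, bi, bj, eligible):
    # pragma: no cover - numba
    i = bi
    j = bj
    n_cols = 0
    n_ident = 0
    state = 0  # 0 = H, 1 = E (gap in query), 2 = F (gap in subject)
    while True:
        if state == 0:
            if H[i, j] == 0:
                break
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + matrix[a[i - 1], b[j - 1]]:
                n_cols += 1
                if a[i - 1] == b[j - 1] and eligible[a[i - 1]]:
                    n_ident += 1
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            n_cols += 1
            if E[i, j] == H[i, j - 1] + gap_open:
                state = 0
            j -= 1
        else:
            n_cols += 1
            if F[i, j] == H[i - 1, j] + gap_open:
                state = 0
            i -= 1
    return i, j, n_cols, n_ident


def _align_window(
    a_codes: np.ndarray,
    b_codes: np.ndarray,
    scoring: ScoringScheme,
    subject_offset: int,
    query_id: str,
    subject_id: str,
    query_len: int,
    subject_len: int,
) -> Optional[LocalAlignment]:
    H, E, F, best, bi, bj = _sw_fill(
        a_codes, b_codes, scoring.matrix, scoring.gap_open, scoring.gap_extend
    )
    if best <= 0:
        return None
    eligible = scoring.identity_eligible()
    i0, j0, n_cols, n_ident = _sw_traceback(
        a_codes, b_codes, H, E, F, scoring.matrix,
        scoring.gap_open, scoring.gap_extend, bi, bj, eligible,
    )
    q_span = (i0, bi)
    s_span = (j0 + subject_offset, bj + subject_offset)
    return LocalAlignment(
        query_id=query_id,
        subject_id=subject_id,
        score=int(best),
        identity_pct=100.0 * n_ident / n_cols,
        alignment_length=int(n_cols),
        query_span=q_span,
        subject_span=s_span,
        query_coverage=(q_span[1] - q_span[0]) / query_len,
        subject_coverage=(s_span[1] - s_span[0]) / subject_len,
    )


def kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    """Exact k-mer position index of a subject sequence (uppercased)."""
    s = seq.upper()
    index: dict[str, list[int]] = {}
    for i in range(len(s) - k + 1):
        index.setdefault(s[i : i + k], []).append(i)
    return index


def _best_diagonal(query: str, index: Mapping[str, list[int]], k: int) -> Optional[int]:
    q = query.upper()
    votes: dict[int, int] = {}
    for i in range(len(q) - k + 1):
        positions = index.get(q[i : i + k])
        if positions is None:
            continue
        for j in positions:
            d = j - i
            votes[d] = votes.get(d, 0) + 1
    if not votes:
        return None
    # Most-supported diagonal; deterministic tie-break on the diagonal value.
    return max(votes, key=lambda d: (votes[d], -abs(d)))


def local_align(
    a: str,
    b: str,
    scoring: ScoringScheme,
    query_id: str = "query",
    subject_id: str = "subject",
    max_full_cells: int = 4_000_000,
    subject_index: Optional[Mapping[str, list[int]]] = None,
) -> Optional[LocalAlignment]:
    """Optimal local alignment of ``a`` (query) against ``b`` (subject).

    Returns ``None`` when no alignment with positive score exists, or when the
    seeded path finds no anchor for an oversized problem.  Exact for all
    problems up to ``max_full_cells`` DP cells; seeded-and-banded beyond that.
    """
    a_codes = scoring.encode(a)
    b_codes = scoring.encode(b)
    if len(a) * len(b) <= max_full_cells:
        return _align_window(
            a_codes, b_codes, scoring, 0, query_id, subject_id, len(a), len(b)
        )
    k = _SEED_K[scoring.kind]
    index = subject_index if subject_index is not None else kmer_index(b, k)
    diag = _best_diagonal(a, index, k)
    if diag is None:
        return None
    lo = max(0, diag - _WINDOW_PAD)
    hi = min(len(b), diag + len(a) + _WINDOW_PAD)
    return _align_window(
        a_codes, b_codes[lo:hi], scoring, lo, query_id, subject_id, len(a), len(b)
    )


def best_local_hit(
    query: str,
    subjects: Mapping[str, str],
    scoring: ScoringScheme,
    query_id: str = "query",
    **kwargs,
) -> Optional[LocalAlignment]:
    """Highest-scoring local alignment of ``query`` against a subject set.

    Ties are broken by higher identity, then lexicographically smallest
    subject id.
    """
    if not subjects:
        raise ValueError("subject collection is empty")
    best: Optional[LocalAlignment] = None
    for sid in sorted(subjects):
        aln = local_align(query, subjects[sid], scoring, query_id=query_id,
                          subject_id=sid, **kwargs)
        if aln is None:
            continue
        if best is None or (aln.score, aln.identity_pct) > (best.score, best.identity_pct):
            best = aln
    return best
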