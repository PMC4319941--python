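"""Whole-genome distance statistics: fragment-based ANI and best-hit AAI.

ANI follows the fragment protocol: each assembly is cut into consecutive
1020-nt windows, every fragment is aligned against the other assembly, and a
fragment is retained when its best hit reaches at least 30% identity over at
least 70% of the fragment length.  The directional value is the mean identity
of retained fragments and the reported ANI is the reciprocal mean of the two
directions.

AAI aligns every protein of one proteome against the other, discards hits
below 30% identity, shorter than 30 aligned columns, or covering less than
70% of the query protein, keeps the best surviving hit per query, and
averages identities reciprocally.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .align import ScoringScheme, kmer_index, local_align
from .io import InvalidInputError

_NUC_SEED_K = 11


class UndefinedDistanceError(ValueError):
    """No retained fragments/hits in either direction; the distance is undefined."""


@dataclass(frozen=True)
class Fragment:
    fragment_id: str     # "<contig>:<offset>" with a 0-based offset
    sequence: str


@dataclass
class ANIResult:
    genome_a: str
    genome_b: str
    forward_mean_identity: float
    reverse_mean_identity: float
    fragments_total_forward: int
    fragments_retained_forward: int
    fragments_total_reverse: int
    fragments_retained_reverse: int
    ani: float


@dataclass
class AAIResult:
    genome_a: str
    genome_b: str
    forward_hits_retained: int
    reverse_hits_retained: int
    forward_mean_identity: float
    reverse_mean_identity: float
    aai: float


def fragment_genome(
    contigs: Mapping[str, str],
    fragment_length: int = 1020,
    min_tail: int = 100,
) -> list[Fragment]:
    """Cut contigs into consecutive non-overlapping windows.

    The terminal fragment of each contig is kept only when it is at least
    ``min_tail`` nt long.
    """
    if not contigs:
        raise InvalidInputError("empty assembly")
    fragments: list[Fragment] = []
    for contig_id in contigs:
        seq = contigs[contig_id]
        for start in range(0, len(seq), fragment_length):
            piece = seq[start : start + fragment_length]
            if len(piece) < fragment_length and len(piece) < min_tail:
                continue
            fragments.append(Fragment(f"{contig_id}:{start}", piece))
    return fragments


def _directional_ani(
    query_contigs: Mapping[str, str],
    subject_contigs: Mapping[str, str],
    scoring: ScoringScheme,
    fragment_length: int,
    min_identity_pct: float,
    min_coverage: float,
) -> tuple[float, int, int]:
    fragments = fragment_genome(query_contigs, fragment_length)
    indexes = {
        cid: kmer_index(seq, _NUC_SEED_K) for cid, seq in subject_contigs.items()
    }
    identities: list[float] = []
    for frag in fragments:
        best = None
        for cid, seq in subject_contigs.items():
            aln = local_align(
                frag.sequence, seq, scoring,
                query_id=frag.fragment_id, subject_id=cid,
                subject_index=indexes[cid],
            )
            if aln is None:
                continue
            if best is None or (aln.score, aln.identity_pct) > (best.score, best.identity_pct):
                best = aln
        if best is None:
            continue
        if best.identity_pct >= min_identity_pct and best.query_coverage >= min_coverage:
            identities.append(best.identity_pct)
    mean = sum(identities) / len(identities) if identities else float("nan")
    return mean, len(fragments), len(identities)


def ani(
    genome_a: str,
    contigs_a: Mapping[str, str],
    genome_b: str,
    contigs_b: Mapping[str, str],
    scoring: Optional[ScoringScheme] = None,
    fragment_length: int = 1020,
    min_identity_pct: float = 30.0,
    min_coverage: float = 0.7,
    reciprocal: bool = True,
) -> ANIResult:
    """Fragment-based average nucleotide identity between two assemblies."""
    scoring = scoring or ScoringScheme.nucleotide()
    fwd, total_f, kept_f = _directional_ani(
        contigs_a, contigs_b, scoring, fragment_length, min_identity_pct, min_coverage
    )
    if reciprocal:
        rev, total_r, kept_r = _directional_ani(
            contigs_b, contigs_a, scoring, fragment_length, min_identity_pct, min_coverage
        )
    else:
        rev, total_r, kept_r = float("nan"), 0, 0
    retained = [v for v in (fwd, rev) if v == v]  # drop NaNs
    if not retained:
        raise UndefinedDistanceError(
            f"no retained fragments between {genome_a} and {genome_b}"
        )
    return ANIResult(
        genome_a=genome_a,
        genome_b=genome_b,
        forward_mean_identity=fwd,
        reverse_mean_identity=rev,
        fragments_total_forward=total_f,
        fragments_retained_forward=kept_f,
        fragments_total_reverse=total_r,
        fragments_retained_reverse=kept_r,
        ani=sum(retained) / len(retained),
    )


def _directional_aai(
    queries: Mapping[str, str],
    subjects: Mapping[str, str],
    scoring: ScoringScheme,
    min_identity_pct: float,
    min_alignment_length: int,
    min_coverage: float,
) -> tuple[float, int]:
    identities: list[float] = []
    for qid in sorted(queries):
        best = None
        for sid in sorted(subjects):
            aln = local_align(queries[qid], subjects[sid], scoring,
                              query_id=qid, subject_id=sid)
            if aln is None:
                continue
            if aln.identity_pct < min_identity_pct:
                continue
            if aln.alignment_length < min_alignment_length:
                continue
            if aln.query_coverage < min_coverage:
                continue
            if best is None or (aln.score, aln.identity_pct) > (best.score, best.identity_pct):
                best = aln
        if best is not None:
            identities.append(best.identity_pct)
    mean = sum(identities) / len(identities) if identities else float("nan")
    return mean, len(identities)


def aai(
    genome_a: str,
    proteome_a: Mapping[str, str],
    genome_b: str,
    proteome_b: Mapping[str, str],
    scoring: Optional[ScoringScheme] = None,
    min_identity_pct: float = 30.0,
    min_alignment_length: int = 30,
    min_coverage: float = 0.7,
    reciprocal: bool = True,
) -> AAIResult:
    """Filtered best-hit average amino acid identity between two proteomes."""
    if not proteome_a or not proteome_b:
        raise InvalidInputError("empty proteome")
    scoring = scoring or ScoringScheme.protein()
    fwd, kept_f = _directional_aai(
        proteome_a, proteome_b, scoring,
        min_identity_pct, min_alignment_length, min_coverage,
    )
    if reciprocal:
        rev, kept_r = _directional_aai(
            proteome_b, proteome_a, scoring,
            min_identity_pct, min_alignment_length, min_coverage,
        )
    else:
        rev, kept_r = float("nan"), 0
    retained = [v for v in (fwd, rev) if v == v]
    if not retained:
        raise UndefinedDistanceError(
            f"no retained hits between {genome_a} and {genome_b}"
        )
    return AAIResult(
        genome_a=genome_a,
        genome_b=genome_b,
        forward_hits_retained=kept_f,
        reverse_hits_retained=kept_r,
        forward_mean_identity=fwd,
        reverse_mean_identity=rev,
        aai=sum(retained) / len(retained),
    )


def pairwise_matrix(
    values: Mapping[tuple[str, str], float],
    genome_ids: Sequence[str],
    tree_order: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Symmetric genome-by-genome percentage matrix (2-decimal values).

    ``tree_order`` optionally reorders rows/columns, e.g. to match tip order
    of a phylogeny for heatmap display.
    """
    order = list(tree_order) if tree_order is not None else sorted(genome_ids)
    mat = pd.DataFrame(100.0, index=order, columns=order)
    for (a, b), v in values.items():
        mat.at[a, b] = round(v, 2)
        mat.at[b, a] = round(v, 2)
    return mat
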