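"""Independent reference implementations used only to check the package.

These are deliberately written in plain Python with no code shared with the
package internals: an unoptimized full-DP local aligner, a brute-force
clustering oracle built on networkx, exhaustive accumulation-curve
enumeration, and a rank-sum enumeration oracle.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import networkx as nx

NEG = -(10**9)


def sw_reference(a: str, b: str, scoring):
    """Unoptimized affine-gap Smith-Waterman with explicit traceback.

    Traceback preference at each cell: diagonal, then gap-in-query (E), then
    gap-in-subject (F).  Returns ``None`` when the best score is <= 0, else a
    dict with score, spans, alignment length and identical-column count.
    """
    index = {c: i for i, c in enumerate(scoring.alphabet)}
    A = [index[c] for c in a.upper()]
    B = [index[c] for c in b.upper()]
    S = scoring.matrix
    go, ge = scoring.gap_open, scoring.gap_extend
    m, n = len(A), len(B)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best, bi, bj = 0, 0, 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] + go, E[i][j - 1] + ge)
            F[i][j] = max(H[i - 1][j] + go, F[i - 1][j] + ge)
            h = max(0, H[i - 1][j - 1] + S[A[i - 1]][B[j - 1]], E[i][j], F[i][j])
            H[i][j] = h
            if h > best:
                best, bi, bj = h, i, j
    if best <= 0:
        return None
    ambiguous = set("N") if scoring.kind == "nucleotide" else set("BZX")
    i, j = bi, bj
    n_cols = n_ident = 0
    state = "H"
    au, bu = a.upper(), b.upper()
    while True:
        if state == "H":
            if H[i][j] == 0:
                break
            if i > 0 and j > 0 and H[i][j] == H[i - 1][j - 1] + S[A[i - 1]][B[j - 1]]:
                n_cols += 1
                if au[i - 1] == bu[j - 1] and au[i - 1] not in ambiguous:
                    n_ident += 1
                i -= 1
                j -= 1
            elif H[i][j] == E[i][j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            n_cols += 1
            if E[i][j] == H[i][j - 1] + go:
                state = "H"
            j -= 1
        else:
            n_cols += 1
            if F[i][j] == H[i - 1][j] + go:
                state = "H"
            i -= 1
    return {
        "score": best,
        "query_span": (i, bi),
        "subject_span": (j, bj),
        "alignment_length": n_cols,
        "n_ident": n_ident,
    }


def brute_force_partition(gene_ids, same_family) -> set[frozenset]:
    """Connected components over an explicit all-pairs verdict graph."""
    graph = nx.Graph()
    graph.add_nodes_from(gene_ids)
    for x, y in itertools.combinations(gene_ids, 2):
        if same_family(x, y):
            graph.add_edge(x, y)
    return {frozenset(c) for c in nx.connected_components(graph)}


def exhaustive_accumulation(columns: dict[str, set[str]]):
    """Exact mean pan/core curves over all genome orderings."""
    genomes = sorted(columns)
    n = len(genomes)
    pan_sums = [Fraction(0)] * n
    core_sums = [Fraction(0)] * n
    count = 0
    for order in itertools.permutations(genomes):
        union: set[str] = set()
        inter: set[str] | None = None
        for i, g in enumerate(order):
            union = union | columns[g]
            inter = columns[g] if inter is None else inter & columns[g]
            pan_sums[i] += len(union)
            core_sums[i] += len(inter)
        count += 1
    return (
        [float(s / count) for s in pan_sums],
        [float(s / count) for s in core_sums],
    )


def rank_sum_exact(x, y, alternative="two-sided") -> float:
    """Exact rank-sum p-value by direct enumeration (midranks for ties)."""
    pooled = sorted(list(x) + list(y))
    ranks_of = {}
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and pooled[j + 1] == pooled[i]:
            j += 1
        ranks_of[pooled[i]] = (i + j) / 2 + 1
        i = j + 1
    all_ranks = [ranks_of[v] for v in list(x) + list(y)]
    w_obs = sum(all_ranks[: len(x)])
    nx_, n = len(x), len(x) + len(y)
    less = greater = 0
    for combo in itertools.combinations(range(n), nx_):
        w = sum(all_ranks[i] for i in combo)
        if w <= w_obs + 1e-9:
            less += 1
        if w >= w_obs - 1e-9:
            greater += 1
    total = comb(n, nx_)
    if alternative == "less":
        return less / total
    if alternative == "greater":
        return greater / total
    return min(1.0, 2 * min(less / total, greater / total))


def pairwise_f1(predicted: set[frozenset], truth: set[frozenset]) -> float:
    """F1 over co-clustered pairs of two partitions of the same elements."""
    def pairs(partition):
        out = set()
        for group in partition:
            for pair in itertools.combinations(sorted(group), 2):
                out.add(pair)
        return out

    p_pairs, t_pairs = pairs(predicted), pairs(truth)
    if not p_pairs and not t_pairs:
        return 1.0
    tp = len(p_pairs & t_pairs)
    precision = tp / len(p_pairs) if p_pairs else 1.0
    recall = tp / len(t_pairs) if t_pairs else 1.0
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)
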