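"""Rooted trees, outgroup rooting, node-depth statistics and the rank-sum test.

``nodes_to_mrca`` counts the internal nodes on the path from a tip up to and
including the root, excluding the tip itself — so every tip of a two-tip tree
scores 1.  The count depends only on topology, never on branch lengths.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from scipy.stats import norm


class NewickParseError(ValueError):
    """Malformed Newick; carries the character offset of the failure."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at character {offset})")
        self.offset = offset


class NotMonophyleticError(ValueError):
    """The requested outgroup does not form one side of any edge."""


@dataclass
class TreeNode:
    name: Optional[str] = None            # tip label, or internal support label
    length: Optional[float] = None
    children: list["TreeNode"] = field(default_factory=list)
    parent: Optional["TreeNode"] = None

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, child: "TreeNode") -> None:
        child.parent = self
        self.children.append(child)


class RootedTree:
    """A rooted tree with labelled tips and optional branch lengths."""

    def __init__(self, root: TreeNode):
        self.root = root
        labels = [t.name for t in self.tips()]
        if len(labels) != len(set(labels)):
            raise ValueError("tip labels are not unique")

    def tips(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_tip]

    def tip_labels(self) -> list[str]:
        return [t.name or "" for t in self.tips()]

    def preorder(self) -> Iterable[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.preorder() if not n.is_tip]

    def find_tip(self, label: str) -> TreeNode:
        for t in self.tips():
            if t.name == label:
                return t
        raise ValueError(f"unknown tip {label!r}")

    def path_length(self, label_a: str, label_b: str) -> float:
        """Sum of branch lengths on the path between two tips."""
        anc_a = self._ancestry(self.find_tip(label_a))
        anc_b = self._ancestry(self.find_tip(label_b))
        seen = {id(n): dist for n, dist in anc_a}
        for node, dist in anc_b:
            if id(node) in seen:
                return seen[id(node)] + dist
        raise ValueError("tips share no ancestor")  # unreachable on a valid tree

    @staticmethod
    def _ancestry(node: TreeNode) -> list[tuple[TreeNode, float]]:
        out = []
        dist = 0.0
        while node is not None:
            out.append((node, dist))
            dist += node.length or 0.0
            node = node.parent
        return out

    def to_newick(self) -> str:
        return _write_node(self.root) + ";"

    def __repr__(self) -> str:
        return f"RootedTree({len(self.tip_labels())} tips)"


# ---------------------------------------------------------------------------
# Newick grammar


def _format_length(x: float) -> str:
    s = f"{x:.10g}"
    return s


def _write_node(node: TreeNode) -> str:
    if node.is_tip:
        body = _quote_label(node.name or "")
    else:
        inner = ",".join(_write_node(c) for c in node.children)
        body = f"({inner})" + (_quote_label(node.name) if node.name else "")
    if node.length is not None:
        body += f":{_format_length(node.length)}"
    return body


def _quote_label(label: str) -> str:
    if any(c in label for c in "():;, \t'[]"):
        return "'" + label.replace("'", "''") + "'"
    return label


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def fail(self, message: str):
        raise NewickParseError(message, self.pos)

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos] in " \t\r\n":
            self.pos += 1

    def parse(self) -> TreeNode:
        self.skip_ws()
        node = self.parse_node()
        self.skip_ws()
        if self.peek() != ";":
            self.fail("expected ';'")
        self.pos += 1
        self.skip_ws()
        if self.pos != len(self.text):
            self.fail("trailing characters after ';'")
        return node

    def parse_node(self) -> TreeNode:
        self.skip_ws()
        node = TreeNode()
        if self.peek() == "(":
            self.pos += 1
            while True:
                node.add_child(self.parse_node())
                self.skip_ws()
                if self.peek() == ",":
                    self.pos += 1
                    continue
                if self.peek() == ")":
                    self.pos += 1
                    break
                self.fail("expected ',' or ')'")
            label = self.parse_label()
            node.name = label or None
        else:
            label = self.parse_label()
            if not label:
                self.fail("expected a tip label")
            node.name = label
        self.skip_ws()
        if self.peek() == ":":
            self.pos += 1
            node.length = self.parse_number()
        return node

    def parse_label(self) -> str:
        self.skip_ws()
        if self.peek() == "'":
            self.pos += 1
            out = []
            while True:
                if self.pos >= len(self.text):
                    self.fail("unterminated quoted label")
                c = self.text[self.pos]
                if c == "'":
                    if self.text[self.pos : self.pos + 2] == "''":
                        out.append("'")
                        self.pos += 2
                        continue
                    self.pos += 1
                    return "".join(out)
                out.append(c)
                self.pos += 1
        out = []
        while self.peek() and self.peek() not in "():;,'[] \t\r\n":
            out.append(self.text[self.pos])
            self.pos += 1
        return "".join(out)

    def parse_number(self) -> float:
        start = self.pos
        while self.peek() and self.peek() in "+-0123456789.eE":
            self.pos += 1
        token = self.text[start : self.pos]
        try:
            return float(token)
        except ValueError:
            self.pos = start
            self.fail(f"invalid branch length {token!r}")


def parse_newick(text: str) -> RootedTree:
    """Parse a Newick string (branch lengths, support labels, quoted labels)."""
    return RootedTree(_Parser(text).parse())


def read_newick(path) -> RootedTree:
    with open(path) as fh:
        return parse_newick(fh.read().strip())


# ---------------------------------------------------------------------------
# Rooting


def root_with_outgroup(tree: RootedTree, outgroup: Sequence[str]) -> RootedTree:
    """Reroot on the edge separating the outgroup tips from everything else.

    Branch lengths are preserved (the split edge's length is divided evenly
    between the two new root edges).  Raises :class:`NotMonophyleticError`
    when no single edge separates the outgroup from the ingroup.
    """
    out_set = set(outgroup)
    all_tips = set(tree.tip_labels())
    if not out_set or not out_set <= all_tips:
        raise ValueError("outgroup must be a non-empty subset of tip labels")
    if out_set == all_tips:
        raise NotMonophyleticError("outgroup cannot contain every tip")

    # Work on an undirected copy; find the edge bipartitioning out_set.
    adjacency, lengths, names, tips = _as_undirected(tree)
    edge = _separating_edge(adjacency, tips, out_set)
    if edge is None:
        raise NotMonophyleticError(f"outgroup {sorted(out_set)} is not separable")
    u, v = edge
    half = lengths.get(frozenset(edge))
    root = TreeNode()
    for start, other in ((u, v), (v, u)):
        child = _build_rooted(start, other, adjacency, lengths, names, tips)
        child.length = half / 2 if half is not None else None
        root.add_child(child)
    # Put the ingroup-side child second so child order is outgroup-first.
    first_tips = _tipset(root.children[0])
    if not first_tips <= out_set:
        root.children.reverse()
    return RootedTree(root)


def _as_undirected(tree: RootedTree):
    adjacency: dict[int, list[int]] = {}
    lengths: dict[frozenset, Optional[float]] = {}
    names: dict[int, Optional[str]] = {}
    tips: dict[int, str] = {}
    nodes = list(tree.preorder())
    index = {id(n): i for i, n in enumerate(nodes)}
    for n in nodes:
        i = index[id(n)]
        adjacency.setdefault(i, [])
        names[i] = n.name
        if n.is_tip:
            tips[i] = n.name or ""
        if n.parent is not None:
            j = index[id(n.parent)]
            adjacency[i].append(j)
            adjacency.setdefault(j, []).append(i)
            lengths[frozenset((i, j))] = n.length
    # Suppress a degree-2 root so the bipartition set matches the unrooted tree.
    root_i = index[id(tree.root)]
    if len(adjacency[root_i]) == 2 and root_i not in tips:
        a, b = adjacency[root_i]
        la = lengths.pop(frozenset((root_i, a)), None)
        lb = lengths.pop(frozenset((root_i, b)), None)
        merged = None if la is None and lb is None else (la or 0.0) + (lb or 0.0)
        adjacency[a].remove(root_i)
        adjacency[b].remove(root_i)
        adjacency[a].append(b)
        adjacency[b].append(a)
        del adjacency[root_i]
        lengths[frozenset((a, b))] = merged
    return adjacency, lengths, names, tips


def _tips_below(start: int, parent: int, adjacency, tips) -> set[str]:
    found = set()
    stack = [(start, parent)]
    while stack:
        node, avoid = stack.pop()
        if node in tips:
            found.add(tips[node])
        for nbr in adjacency[node]:
            if nbr != avoid:
                stack.append((nbr, node))
    return found


def _separating_edge(adjacency, tips, out_set) -> Optional[tuple[int, int]]:
    seen = set()
    for u in adjacency:
        for v in adjacency[u]:
            key = frozenset((u, v))
            if key in seen:
                continue
            seen.add(key)
            side = _tips_below(u, v, adjacency, tips)
            if side == out_set or (set(tips.values()) - side) == out_set:
                return (u, v) if side == out_set else (v, u)
    return None


def _build_rooted(node: int, parent: int, adjacency, lengths, names, tips) -> TreeNode:
    out = TreeNode(name=tips.get(node, names.get(node)))
    for nbr in adjacency[node]:
        if nbr == parent:
            continue
        child = _build_rooted(nbr, node, adjacency, lengths, names, tips)
        child.length = lengths.get(frozenset((node, nbr)))
        out.add_child(child)
    return out


def _tipset(node: TreeNode) -> set[str]:
    if node.is_tip:
        return {node.name or ""}
    out: set[str] = set()
    for c in node.children:
        out |= _tipset(c)
    return out


def bipartitions(tree: RootedTree) -> set[frozenset]:
    """Non-trivial tip bipartitions of the unrooted topology (smaller side)."""
    all_tips = frozenset(tree.tip_labels())
    parts: set[frozenset] = set()
    for node in tree.preorder():
        if node is tree.root or node.is_tip:
            continue
        side = frozenset(_tipset(node))
        other = all_tips - side
        if len(side) < 2 or len(other) < 2:
            continue
        parts.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return parts


# ---------------------------------------------------------------------------
# Node-depth statistic


@dataclass(frozen=True)
class NodeDepthRecord:
    tip_id: str
    host: Optional[str]
    nodes_to_mrca: int


def nodes_to_mrca(tree: RootedTree, tip_label: str, mrca: Optional[TreeNode] = None) -> int:
    """Internal nodes on the path from a tip up to (and including) the MRCA."""
    node = tree.find_tip(tip_label)
    target = mrca if mrca is not None else tree.root
    count = 0
    while node is not target:
        node = node.parent
        if node is None:
            raise ValueError(f"tip {tip_label!r} is not a descendant of the MRCA")
        count += 1
    return count


def node_depth_report(
    tree: RootedTree, hosts: Optional[dict[str, str]] = None
) -> list[NodeDepthRecord]:
    hosts = hosts or {}
    return [
        NodeDepthRecord(label, hosts.get(label), nodes_to_mrca(tree, label))
        for label in tree.tip_labels()
    ]


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum (two-sample) test


@dataclass(frozen=True)
class WilcoxonResult:
    rank_sum_statistic: float
    p_value: float
    alternative: str
    method: str


def _midranks(values: Sequence[float]) -> list[float]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    method: str = "auto",
) -> WilcoxonResult:
    """Wilcoxon two-sample (rank-sum) test with midranks for ties.

    ``method='exact'`` enumerates all assignments of the pooled ranks to the
    two groups; ``'normal'`` uses the tie-corrected normal approximation with
    continuity correction.  ``'auto'`` picks exact when ``min(nx, ny) <= 10``
    and ``nx + ny <= 20``.  The statistic is the rank sum of ``x``.
    """
    if not len(x) or not len(y):
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    nx, ny = len(x), len(y)
    n = nx + ny
    ranks = _midranks(list(x) + list(y))
    w = sum(ranks[:nx])
    if method == "auto":
        method = "exact" if (min(nx, ny) <= 10 and n <= 20) else "normal"
    if method == "exact":
        total = math.comb(n, nx)
        n_le = n_ge = 0
        eps = 1e-9
        for combo in itertools.combinations(range(n), nx):
            s = sum(ranks[i] for i in combo)
            if s <= w + eps:
                n_le += 1
            if s >= w - eps:
                n_ge += 1
        p_less = n_le / total
        p_greater = n_ge / total
        if alternative == "less":
            p = p_less
        elif alternative == "greater":
            p = p_greater
        else:
            p = min(1.0, 2 * min(p_less, p_greater))
        return WilcoxonResult(w, p, alternative, "exact")
    # Normal approximation with tie correction and continuity correction.
    mu = nx * (n + 1) / 2
    tie_counts: dict[float, int] = {}
    for r in ranks:
        tie_counts[r] = tie_counts.get(r, 0) + 1
    tie_term = sum(c**3 - c for c in tie_counts.values())
    var = nx * ny / 12 * ((n + 1) - tie_term / (n * (n - 1)))
    if var == 0:
        return WilcoxonResult(w, 1.0, alternative, "normal-approximation")
    sd = math.sqrt(var)
    if alternative == "less":
        p = float(norm.cdf((w - mu + 0.5) / sd))
    elif alternative == "greater":
        p = float(norm.sf((w - mu - 0.5) / sd))
    else:
        z = (w - mu - math.copysign(0.5, w - mu)) / sd if w != mu else 0.0
        p = float(min(1.0, 2 * norm.sf(abs(z))))
    return WilcoxonResult(w, p, alternative, "normal-approximation")


# ---------------------------------------------------------------------------
# Alignment concatenation


def concatenate_alignments(
    blocks: dict[str, dict[str, str]], gap_char: str = "-"
) -> tuple[dict[str, str], list[tuple[str, int, int]]]:
    """Join per-family aligned blocks into one supermatrix.

    Blocks are concatenated in sorted family-id order; genomes absent from a
    block get gap padding.  Returns the supermatrix and a partition table of
    1-based inclusive column ranges per block.
    """
    genomes: set[str] = set()
    widths: dict[str, int] = {}
    for fam_id in blocks:
        rows = blocks[fam_id]
        if not rows:
            raise ValueError(f"block {fam_id!r} is empty")
        lengths = {len(s) for s in rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"block {fam_id!r} has ragged rows")
        widths[fam_id] = lengths.pop()
        genomes |= set(rows)
    matrix = {g: [] for g in sorted(genomes)}
    partitions: list[tuple[str, int, int]] = []
    col = 0
    for fam_id in sorted(blocks):
        width = widths[fam_id]
        partitions.append((fam_id, col + 1, col + width))
        col += width
        for g in matrix:
            matrix[g].append(blocks[fam_id].get(g, gap_char * width))
    return {g: "".join(parts) for g, parts in matrix.items()}, partitions
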