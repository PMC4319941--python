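"""Synthetic genome-clade generator with known ground truth.

A Yule (pure-birth) tree with exponential branch lengths carries a gene
repertoire evolving by Poisson gain and exponential loss, and codon-structured
gene sequences plus intergenic spacers evolving by per-site substitution.
Every downstream stage (family clustering, pan/core curves, ANI/AAI, host
cores, tree statistics) can be validated against the recorded truth: the tree
itself, the true presence/absence matrix, realized pairwise identities and
host labels.

One global seed drives named sub-streams (tree, repertoire, sequences, hosts)
so each stage is independently reproducible; fixed seeds give byte-identical
output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from Bio.Seq import Seq

from .io import write_fasta
from .pancore import PresenceAbsenceMatrix
from .phylo import RootedTree, TreeNode

_BASES = "ACGT"
_STOP_CODONS = {(3, 0, 0), (3, 0, 2), (3, 2, 0)}  # TAA, TAG, TGA
_SENSE_CODONS = np.array(
    [
        (i, j, k)
        for i in range(4)
        for j in range(4)
        for k in range(4)
        if (i, j, k) not in _STOP_CODONS
    ],
    dtype=np.int8,
)

_STREAMS = {"tree": 0, "repertoire": 1, "sequences": 2, "hosts": 3}


def _substream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[name],))
    )


@dataclass(frozen=True)
class SimulationConfig:
    n_genomes: int = 10
    ancestral_family_count: int = 40
    gain_rate: float = 1.0            # gains per unit branch length
    loss_rate: float = 0.2            # per-family loss hazard per unit branch length
    substitution_rate: float = 0.02   # per-site hazard per unit branch length
    mean_gene_length_aa: int = 100
    host_labels: tuple[str, ...] = ("bee", "human")
    host_mode: str = "clade"          # "clade" | "random"
    branch_scale: float = 1.0         # mean of the exponential branch lengths
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 2:
            raise ValueError("n_genomes must be >= 2")
        if self.ancestral_family_count < 1:
            raise ValueError("ancestral_family_count must be >= 1")
        if self.gain_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be >= 0")
        if not 0 <= self.substitution_rate < 1:
            raise ValueError("substitution_rate must be in [0, 1)")
        if self.mean_gene_length_aa < 30:
            raise ValueError("mean_gene_length_aa must be >= 30")
        if self.host_mode not in ("clade", "random"):
            raise ValueError(f"unknown host_mode {self.host_mode!r}")


@dataclass
class SyntheticGenome:
    genome_id: str
    contigs: dict[str, str]
    cds: dict[str, str]        # gene id -> nucleotide CDS
    proteins: dict[str, str]   # gene id -> protein


@dataclass
class SyntheticTruth:
    true_tree: RootedTree
    true_presence: PresenceAbsenceMatrix
    expected_pairwise_identity: dict[tuple[str, str], float]
    host_labels: dict[str, str]
    gene_to_family: dict[str, str] = field(default_factory=dict)

    def identity(self, a: str, b: str) -> float:
        if a == b:
            return 100.0
        return self.expected_pairwise_identity[(min(a, b), max(a, b))]


# ---------------------------------------------------------------------------
# Tree


def simulate_tree(n_tips: int, seed: int, branch_scale: float = 1.0) -> RootedTree:
    """Yule pure-birth topology with i.i.d. exponential branch lengths.

    Tips are labelled ``G01..GN``; deterministic for a fixed seed.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = _substream(seed, "tree")
    root = TreeNode()
    leaves = []
    for _ in range(2):
        child = TreeNode()
        root.add_child(child)
        leaves.append(child)
    while len(leaves) < n_tips:
        idx = int(rng.integers(len(leaves)))
        node = leaves.pop(idx)
        for _ in range(2):
            child = TreeNode()
            node.add_child(child)
            leaves.append(child)
    width = max(2, len(str(n_tips)))
    counter = 0
    stack = [root]
    while stack:
        node = stack.pop()
        if node is not root:
            node.length = float(rng.exponential(branch_scale))
        if node.is_tip:
            counter += 1
            node.name = f"G{counter:0{width}d}"
        stack.extend(reversed(node.children))
    return RootedTree(root)


# ---------------------------------------------------------------------------
# Repertoire (gain / loss)


def simulate_repertoire(tree: RootedTree, config: SimulationConfig) -> PresenceAbsenceMatrix:
    """Evolve family presence along the tree by Poisson gain and exponential loss.

    The root carries ``ancestral_family_count`` families; along each branch of
    length t every present family is lost with probability ``1 - exp(-loss*t)``
    and ``Poisson(gain*t)`` new families appear, present in the subtree below.
    Families absent from every tip are dropped from the returned matrix.
    """
    rng = _substream(config.seed, "repertoire")
    counter = [config.ancestral_family_count]
    width = 5
    ancestral = [f"F{i + 1:0{width}d}" for i in range(config.ancestral_family_count)]
    tip_sets: dict[str, set[str]] = {}

    def descend(node: TreeNode, present: list[str]) -> None:
        if node.is_tip:
            tip_sets[node.name or ""] = set(present)
            return
        for child in node.children:
            t = child.length or 0.0
            survive_p = float(np.exp(-config.loss_rate * t))
            kept = [f for f in present if rng.random() < survive_p]
            n_new = int(rng.poisson(config.gain_rate * t))
            new = []
            for _ in range(n_new):
                counter[0] += 1
                new.append(f"F{counter[0]:0{width}d}")
            descend(child, kept + new)

    descend(tree.root, ancestral)
    return PresenceAbsenceMatrix.from_sets(tip_sets)


# ---------------------------------------------------------------------------
# Sequences


def _random_gene(rng: np.random.Generator, length_aa: int) -> np.ndarray:
    codons = _SENSE_CODONS[rng.integers(len(_SENSE_CODONS), size=length_aa - 1)]
    return np.concatenate([np.array([0, 3, 2], dtype=np.int8), codons.ravel()])  # ATG + body


def _mutate(
    rng: np.random.Generator, arr: np.ndarray, p: float, coding: bool
) -> np.ndarray:
    out = arr.copy()
    if p <= 0:
        return out
    hits = np.flatnonzero(rng.random(len(arr)) < p)
    for i in hits:
        shifts = rng.permutation(3) + 1
        for shift in shifts:
            candidate = (out[i] + shift) % 4
            if not coding:
                out[i] = candidate
                break
            old = out[i]
            out[i] = candidate
            c = 3 * (i // 3)
            if tuple(out[c : c + 3]) not in _STOP_CODONS:
                break
            out[i] = old
    return out


def _decode(arr: np.ndarray) -> str:
    return "".join(_BASES[b] for b in arr)


def simulate_sequences(
    tree: RootedTree,
    presence: PresenceAbsenceMatrix,
    config: SimulationConfig,
) -> tuple[dict[str, SyntheticGenome], SyntheticTruth]:
    """Evolve gene and spacer sequences along the tree and emit genomes.

    Each family receives a codon-structured ancestral CDS (no internal stops)
    and a 50-200 nt intergenic spacer; both mutate per site with probability
    ``1 - exp(-substitution_rate * t)`` per branch.  A tip genome is the
    concatenation spacer+gene over families (genes only where present), so the
    assembly differs from the plain CDS concatenation.  Realized pairwise
    identities are computed from the emitted sequences: whole-genome Hamming
    when two tips share identical family content, otherwise over the CDS of
    shared families.
    """
    tip_labels = set(presence.genome_ids)
    missing = tip_labels.symmetric_difference(tree.tip_labels())
    if missing:
        raise ValueError(f"presence matrix and tree tips disagree: {sorted(missing)}")
    rng = _substream(config.seed, "sequences")
    families = presence.family_ids
    genes: dict[str, np.ndarray] = {}
    spacers: dict[str, np.ndarray] = {}
    for fam in families:
        length_aa = max(30, int(rng.poisson(config.mean_gene_length_aa)))
        genes[fam] = _random_gene(rng, length_aa)
        spacers[fam] = rng.integers(0, 4, size=int(rng.integers(50, 201))).astype(np.int8)
    terminal_spacer = rng.integers(0, 4, size=int(rng.integers(50, 201))).astype(np.int8)

    tip_state: dict[str, tuple[dict[str, np.ndarray], dict[str, np.ndarray], np.ndarray]] = {}

    def descend(node: TreeNode, g: dict, s: dict, term: np.ndarray) -> None:
        if node.is_tip:
            tip_state[node.name or ""] = (g, s, term)
            return
        for child in node.children:
            t = child.length or 0.0
            p = 1.0 - float(np.exp(-config.substitution_rate * t))
            g2 = {f: _mutate(rng, arr, p, coding=True) for f, arr in g.items()}
            s2 = {f: _mutate(rng, arr, p, coding=False) for f, arr in s.items()}
            descend(child, g2, s2, _mutate(rng, term, p, coding=False))

    descend(tree.root, genes, spacers, terminal_spacer)

    genomes: dict[str, SyntheticGenome] = {}
    gene_to_family: dict[str, str] = {}
    for gid in sorted(tip_labels):
        g, s, term = tip_state[gid]
        fams_here = presence.families_of(gid)
        parts: list[np.ndarray] = []
        cds: dict[str, str] = {}
        proteins: dict[str, str] = {}
        for fam in families:
            parts.append(s[fam])
            if fam in fams_here:
                parts.append(g[fam])
                nt = _decode(g[fam])
                gene_id = f"{gid}_{fam}"
                cds[gene_id] = nt
                proteins[gene_id] = str(Seq(nt).translate(table=11))
                gene_to_family[gene_id] = fam
        parts.append(term)
        contig = _decode(np.concatenate(parts))
        genomes[gid] = SyntheticGenome(gid, {f"{gid}_chr": contig}, cds, proteins)

    identity: dict[tuple[str, str], float] = {}
    ids = sorted(tip_labels)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            fams_a = presence.families_of(a)
            fams_b = presence.families_of(b)
            ga, sa, ta = tip_state[a]
            gb, sb, tb = tip_state[b]
            if fams_a == fams_b:
                seq_a = np.concatenate(
                    [x for f in families for x in ((sa[f], ga[f]) if f in fams_a else (sa[f],))]
                    + [ta]
                )
                seq_b = np.concatenate(
                    [x for f in families for x in ((sb[f], gb[f]) if f in fams_b else (sb[f],))]
                    + [tb]
                )
            else:
                shared = sorted(fams_a & fams_b)
                if not shared:
                    identity[(a, b)] = float("nan")
                    continue
                seq_a = np.concatenate([ga[f] for f in shared])
                seq_b = np.concatenate([gb[f] for f in shared])
            frac = float(np.mean(seq_a != seq_b))
            identity[(a, b)] = 100.0 * (1.0 - frac)

    truth = SyntheticTruth(
        true_tree=tree,
        true_presence=presence,
        expected_pairwise_identity=identity,
        host_labels={},
        gene_to_family=gene_to_family,
    )
    return genomes, truth


# ---------------------------------------------------------------------------
# Hosts


def assign_hosts(
    tree: RootedTree,
    labels: tuple[str, ...] = ("bee", "human"),
    mode: str = "clade",
    seed: int = 0,
) -> dict[str, str]:
    """Assign host labels to tips.

    ``clade`` mode labels the deepest clades (starting from the root's
    children, splitting the largest clade until there are enough groups) so
    hosts are monophyletic; ``random`` mode shuffles tips into equal groups
    as a negative control.
    """
    tips = tree.tip_labels()
    if mode == "random":
        rng = _substream(seed, "hosts")
        order = [tips[i] for i in rng.permutation(len(tips))]
        out = {}
        for i, tip in enumerate(order):
            out[tip] = labels[i * len(labels) // len(tips)]
        return out
    groups: list[TreeNode] = list(tree.root.children)
    while len(groups) < len(labels):
        groups.sort(key=lambda n: -len(_clade_tips(n)))
        biggest = groups.pop(0)
        if biggest.is_tip:
            groups.append(biggest)
            break
        groups.extend(biggest.children)
    out = {}
    for label, node in zip(labels, groups):
        for tip in _clade_tips(node):
            out[tip] = label
    leftover = labels[-1]
    for node in groups[len(labels):]:
        for tip in _clade_tips(node):
            out[tip] = leftover
    return out


def _clade_tips(node: TreeNode) -> list[str]:
    if node.is_tip:
        return [node.name or ""]
    out = []
    for c in node.children:
        out.extend(_clade_tips(c))
    return out


# ---------------------------------------------------------------------------
# One-call dataset


@dataclass
class SimulationResult:
    config: SimulationConfig
    tree: RootedTree
    genomes: dict[str, SyntheticGenome]
    truth: SyntheticTruth


def simulate_dataset(config: SimulationConfig) -> SimulationResult:
    tree = simulate_tree(config.n_genomes, config.seed, config.branch_scale)
    presence = simulate_repertoire(tree, config)
    genomes, truth = simulate_sequences(tree, presence, config)
    truth.host_labels = assign_hosts(tree, config.host_labels, config.host_mode, config.seed)
    return SimulationResult(config, tree, genomes, truth)


def write_dataset(result: SimulationResult, out_dir: str | Path) -> None:
    """Write assemblies, CDS/protein FASTA, hosts TSV, tree Newick and truth JSON."""
    out = Path(out_dir)
    for sub in ("assemblies", "cds", "proteins"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    for gid in sorted(result.genomes):
        genome = result.genomes[gid]
        write_fasta(out / "assemblies" / f"{gid}.fna", genome.contigs)
        write_fasta(
            out / "cds" / f"{gid}.ffn",
            {f"{gid}|{g}": seq for g, seq in genome.cds.items()},
        )
        write_fasta(
            out / "proteins" / f"{gid}.faa",
            {f"{gid}|{g}": seq for g, seq in genome.proteins.items()},
        )
    with open(out / "hosts.tsv", "w") as fh:
        fh.write("genome_id\thost\n")
        for gid in sorted(result.truth.host_labels):
            fh.write(f"{gid}\t{result.truth.host_labels[gid]}\n")
    with open(out / "tree.nwk", "w") as fh:
        fh.write(result.tree.to_newick() + "\n")
    truth = result.truth
    payload = {
        "presence": {
            fam: sorted(
                g for g in truth.true_presence.genome_ids
                if truth.true_presence.df.at[fam, g]
            )
            for fam in truth.true_presence.family_ids
        },
        "expected_pairwise_identity": {
            f"{a}|{b}": v for (a, b), v in truth.expected_pairwise_identity.items()
        },
        "host_labels": truth.host_labels,
        "gene_to_family": truth.gene_to_family,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in result.config.__dict__.items()
        },
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
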