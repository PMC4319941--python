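"""Shared I/O: FASTA reading/writing, genome records, summaries, run configuration.

Conventions
-----------
* CDS/protein FASTA headers follow ``genomeID|geneID [description]``.
* All coordinates in internal records and TSV outputs are 0-based, half-open.
* Sequences are uppercased on read; CRLF line endings are tolerated.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import yaml
from Bio.Seq import Seq


class InvalidInputError(ValueError):
    """Malformed or inconsistent input data."""


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Parse a (multi-record) FASTA file into ``{id: uppercased sequence}``.

    Handles wrapped or unwrapped lines and Windows line endings.  The record
    id is the first whitespace-delimited token of the header.
    """
    path = Path(path)
    records: dict[str, str] = {}
    name: Optional[str] = None
    chunks: list[str] = []
    with open(path, "r", newline="") as fh:
        for raw in fh:
            line = raw.rstrip("\r\n")
            if line.startswith(">"):
                if name is not None:
                    records[name] = "".join(chunks).upper()
                name = line[1:].split()[0] if line[1:].split() else ""
                if not name:
                    raise InvalidInputError(f"{path}: FASTA record with empty id")
                if name in records:
                    raise InvalidInputError(f"{path}: duplicate record id {name!r}")
                chunks = []
            elif line.strip():
                if name is None:
                    raise InvalidInputError(f"{path}: sequence before first header")
                chunks.append(line.strip())
    if name is not None:
        records[name] = "".join(chunks).upper()
    if not records:
        raise InvalidInputError(f"{path}: empty FASTA file")
    return records


def write_fasta(path: str | Path, records: dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in records:
            fh.write(f">{name}\n")
            seq = records[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Genome records


@dataclass
class GeneRecord:
    """One coding sequence: identifiers plus nucleotide and protein sequence."""

    gene_id: str
    genome_id: str
    protein: str
    nucleotide: Optional[str] = None

    @property
    def protein_length(self) -> int:
        return len(self.protein)


@dataclass
class GenomeRecord:
    """One genome: assembly contigs plus its CDS set and optional metadata."""

    genome_id: str
    contigs: dict[str, str] = field(default_factory=dict)
    genes: list[GeneRecord] = field(default_factory=list)
    host: Optional[str] = None
    source: Optional[str] = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise InvalidInputError(
                    f"genome {self.genome_id}: duplicate gene id {g.gene_id!r}"
                )
            seen.add(g.gene_id)


def _split_header(header: str, path: Path) -> tuple[str, str]:
    if "|" not in header:
        raise InvalidInputError(
            f"{path}: header {header!r} does not follow 'genomeID|geneID'"
        )
    genome_id, gene_id = header.split("|", 1)
    return genome_id, gene_id


def read_genome_set(
    directory: str | Path,
    assembly_suffix: str = ".fna",
    cds_suffix: str = ".ffn",
    protein_suffix: str = ".faa",
) -> list[GenomeRecord]:
    """Load all genomes from a directory of per-genome FASTA files.

    A genome is any stem carrying at least one of the three suffixes; protein
    and CDS files use ``genomeID|geneID`` headers.  When both nucleotide and
    protein sequences are present the translation is cross-checked (warning
    on mismatch, not an error).
    """
    directory = Path(directory)
    stems: dict[str, dict[str, Path]] = {}
    for suffix, kind in ((assembly_suffix, "assembly"), (cds_suffix, "cds"),
                         (protein_suffix, "protein")):
        for p in sorted(directory.glob(f"*{suffix}")):
            stems.setdefault(p.name[: -len(suffix)], {})[kind] = p
    if not stems:
        raise InvalidInputError(f"no genome FASTA files found under {directory}")
    genomes: list[GenomeRecord] = []
    for stem in sorted(stems):
        files = stems[stem]
        contigs = read_fasta(files["assembly"]) if "assembly" in files else {}
        nuc: dict[str, str] = {}
        if "cds" in files:
            for header, seq in read_fasta(files["cds"]).items():
                gid, gene = _split_header(header, files["cds"])
                nuc[gene] = seq
        genes: list[GeneRecord] = []
        if "protein" in files:
            for header, seq in read_fasta(files["protein"]).items():
                gid, gene = _split_header(header, files["protein"])
                if gid != stem:
                    raise InvalidInputError(
                        f"{files['protein']}: header genome {gid!r} != file stem {stem!r}"
                    )
                genes.append(GeneRecord(gene, stem, seq.rstrip("*"), nuc.get(gene)))
        elif nuc:
            for gene, seq in nuc.items():
                trimmed = seq[: len(seq) - len(seq) % 3]
                prot = str(Seq(trimmed).translate(table=11)).rstrip("*")
                genes.append(GeneRecord(gene, stem, prot, seq))
        for g in genes:
            if g.nucleotide:
                trimmed = g.nucleotide[: len(g.nucleotide) - len(g.nucleotide) % 3]
                expected = str(Seq(trimmed).translate(table=11)).rstrip("*")
                if expected != g.protein:
                    warnings.warn(
                        f"{stem}|{g.gene_id}: protein does not match CDS translation",
                        stacklevel=2,
                    )
        genomes.append(GenomeRecord(stem, contigs, genes))
    return genomes


def read_host_table(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV ``genome_id<TAB>host`` (header line optional)."""
    hosts: dict[str, str] = {}
    with open(path) as fh:
        for i, raw in enumerate(fh):
            line = raw.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise InvalidInputError(f"{path}:{i + 1}: expected 2 columns")
            if i == 0 and parts[0].lower() in ("genome_id", "genome"):
                continue
            hosts[parts[0]] = parts[1]
    return hosts


def read_annotation_table(path: str | Path) -> dict[str, str]:
    """Read a TSV mapping gene or family ids to COG category letter strings."""
    table: dict[str, str] = {}
    with open(path) as fh:
        for i, raw in enumerate(fh):
            line = raw.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise InvalidInputError(f"{path}:{i + 1}: expected 2 columns")
            if i == 0 and parts[0].lower() in ("gene_id", "family_id", "id"):
                continue
            table[parts[0]] = parts[1]
    return table


# ---------------------------------------------------------------------------
# Summaries


def genome_summary(genome: GenomeRecord) -> dict:
    """Genome size (bp, ambiguity codes included), GC% (A/C/G/T only), CDS count."""
    if not genome.contigs:
        raise InvalidInputError(f"genome {genome.genome_id} has no contigs")
    size = sum(len(s) for s in genome.contigs.values())
    gc = at = 0
    for seq in genome.contigs.values():
        gc += seq.count("G") + seq.count("C")
        at += seq.count("A") + seq.count("T")
    denom = gc + at
    return {
        "genome_id": genome.genome_id,
        "size_bp": size,
        "gc_pct": (100.0 * gc / denom) if denom else float("nan"),
        "cds_count": len(genome.genes),
    }


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Every numeric threshold of the analysis, serialized into result files.

    Defaults: gene families need >50% amino-acid identity covering >50% of
    the longer gene; AAI hits need >=30% identity, >=30 aligned columns and
    >=70% query coverage; ANI uses 1020-nt fragments retained at >=30%
    identity over >=70% of the fragment; 95% is the species cutoff.
    """

    aligner: str = "internal"
    family_identity_pct: float = 50.0
    family_coverage: float = 0.5
    aai_min_identity_pct: float = 30.0
    aai_min_alignment_length: int = 30
    aai_min_coverage: float = 0.7
    ani_fragment_length: int = 1020
    ani_min_identity_pct: float = 30.0
    ani_min_coverage: float = 0.7
    species_cutoff_pct: float = 95.0
    permutations: int = 100
    seed: int = 0
    linkage: str = "single"

    def __post_init__(self) -> None:
        if self.aligner not in ("internal", "blast"):
            raise ValueError(f"unknown aligner backend {self.aligner!r}")
        if self.linkage not in ("single", "complete"):
            raise ValueError(f"unknown linkage mode {self.linkage!r}")
        for name in ("family_identity_pct", "aai_min_identity_pct",
                     "ani_min_identity_pct", "species_cutoff_pct"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} out of range: {v}")
        for name in ("family_coverage", "aai_min_coverage", "ani_min_coverage"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} out of range: {v}")
        if self.ani_fragment_length < 100:
            raise ValueError("ani_fragment_length must be >= 100")
        if self.permutations < 1:
            raise ValueError("permutations must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise InvalidInputError(f"{path}: config must be a flat mapping")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def iter_pairs(ids: Iterable[str]) -> Iterator[tuple[str, str]]:
    """Ordered unique unordered pairs of ids."""
    items = sorted(ids)
    for i, a in enumerate(items):
        for b in items[i + 1 :]:
            yield a, b
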