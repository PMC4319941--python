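"""Host-grouped core-gene-family analysis: per-host cores, Venn regions, COG tabulation."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .io import InvalidInputError
from .pancore import PresenceAbsenceMatrix, core_families

COG_CATEGORIES = "JAKLBDYVTMNZWUOCGEFHIPQRS"


@dataclass
class HostGroupProfile:
    host: str
    genome_ids: list[str]
    core_family_ids: set[str]


def group_core_sets(
    matrix: PresenceAbsenceMatrix,
    host_map: Mapping[str, str],
    hosts: Sequence[str],
    exclude_genomes: Sequence[str] = (),
) -> list[HostGroupProfile]:
    """Per-host core family sets on the shared presence matrix.

    ``exclude_genomes`` drops genomes (e.g. non-gastrointestinal isolates)
    before grouping.  A selected host left with zero genomes is an error.
    """
    excluded = set(exclude_genomes)
    profiles = []
    for host in hosts:
        members = sorted(
            g for g in matrix.genome_ids
            if host_map.get(g) == host and g not in excluded
        )
        if not members:
            raise InvalidInputError(f"host {host!r} has no genomes after exclusions")
        profiles.append(HostGroupProfile(host, members, core_families(matrix, members)))
    return profiles


@dataclass
class VennPartition:
    """Disjoint membership regions of k core sets, keyed by group signature."""

    group_names: list[str]
    regions: dict[frozenset, set[str]] = field(default_factory=dict)

    def region(self, groups: Sequence[str]) -> set[str]:
        return self.regions.get(frozenset(groups), set())

    def unique_to(self, group: str) -> set[str]:
        return self.region([group])

    def shared_by_all(self) -> set[str]:
        return self.region(self.group_names)

    def sizes(self) -> dict[tuple[str, ...], int]:
        return {
            tuple(sorted(sig)): len(fams) for sig, fams in sorted(
                self.regions.items(), key=lambda kv: tuple(sorted(kv[0]))
            )
        }


def venn_partition(core_sets: Mapping[str, set[str]]) -> VennPartition:
    """Assign each family to exactly one region by its membership signature."""
    k = len(core_sets)
    if not 2 <= k <= 5:
        raise ValueError(f"need between 2 and 5 groups, got {k}")
    names = list(core_sets)
    universe = set().union(*core_sets.values())
    regions: dict[frozenset, set[str]] = {}
    for fam in universe:
        signature = frozenset(g for g in names if fam in core_sets[g])
        regions.setdefault(signature, set()).add(fam)
    return VennPartition(names, regions)


@dataclass
class CategoryDistribution:
    counts: dict[str, float]          # fractional when multi-letter labels split
    percentages: dict[str, float]     # over annotated families only
    annotated: float
    unannotated: int


def category_distribution(
    family_ids: Sequence[str],
    annotations: Mapping[str, str],
    multi_letter: str = "fractional",
) -> CategoryDistribution:
    """Tabulate one-letter COG categories over a family set.

    Multi-letter labels (e.g. ``"KL"``) are split fractionally by default
    (0.5 each); ``multi_letter='primary'`` keeps only the first letter.
    Families absent from the annotation map count as unannotated.
    """
    if multi_letter not in ("fractional", "primary"):
        raise ValueError(f"unknown multi_letter mode {multi_letter!r}")
    counts: dict[str, float] = {}
    unannotated = 0
    for fam in family_ids:
        letters = annotations.get(fam, "").strip().upper()
        letters = "".join(c for c in letters if c in COG_CATEGORIES)
        if not letters:
            unannotated += 1
            continue
        if multi_letter == "primary":
            letters = letters[0]
        weight = 1.0 / len(letters)
        for c in letters:
            counts[c] = counts.get(c, 0.0) + weight
    annotated = sum(counts.values())
    percentages = {
        c: 100.0 * v / annotated for c, v in counts.items()
    } if annotated else {}
    return CategoryDistribution(counts, percentages, annotated, unannotated)
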