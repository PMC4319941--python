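"""Stage orchestration: run the full analysis with a manifest and stage skipping.

Stage order is families -> pancore -> ani -> aai -> hostcore -> treestats.
Each completed stage records the digests of its inputs and outputs in
``manifest.json``; re-runs skip stages whose inputs, config and outputs are
all unchanged, and recompute a stage (plus everything downstream of it) when
any of them differ — including a corrupted intermediate file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import aniaai, families, hostcore, pancore, phylo
from .io import (
    InvalidInputError,
    RunConfig,
    read_annotation_table,
    read_genome_set,
    read_host_table,
)
from .pancore import PresenceAbsenceMatrix

logger = logging.getLogger("bactopan")

STAGES = ("families", "pancore", "ani", "aai", "hostcore", "treestats")

# Downstream closure: invalidating a stage invalidates these as well.
_DOWNSTREAM = {
    "families": ("pancore", "hostcore"),
    "pancore": (),
    "ani": (),
    "aai": (),
    "hostcore": (),
    "treestats": (),
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _digest_paths(paths: Sequence[Path]) -> str:
    h = hashlib.sha256()
    for p in sorted(paths):
        h.update(p.name.encode())
        h.update(_sha256(p).encode())
    return h.hexdigest()


class Pipeline:
    def __init__(
        self,
        config: RunConfig,
        input_dir: str | Path,
        out_dir: str | Path,
        compare_hosts: tuple[str, str] = ("bee", "human"),
        host_groups: Optional[Sequence[str]] = None,
        rescue: bool = False,
    ):
        self.config = config
        self.input_dir = Path(input_dir)
        self.out_dir = Path(out_dir)
        self.compare_hosts = compare_hosts
        self.host_groups = list(host_groups) if host_groups else None
        self.rescue = rescue
        self.manifest_path = self.out_dir / "manifest.json"
        self.manifest: dict = {}

    # -- manifest -----------------------------------------------------------

    def _load_manifest(self) -> None:
        if self.manifest_path.exists():
            self.manifest = json.loads(self.manifest_path.read_text())
        else:
            self.manifest = {}

    def _save_manifest(self) -> None:
        self.manifest_path.write_text(json.dumps(self.manifest, indent=1, sort_keys=True))

    def _stage_current(self, stage: str, inputs_digest: str) -> bool:
        entry = self.manifest.get(stage)
        if not entry or not entry.get("complete"):
            return False
        if entry.get("inputs_digest") != inputs_digest:
            return False
        if entry.get("config") != self.config.to_dict():
            return False
        for rel, digest in entry.get("outputs", {}).items():
            path = self.out_dir / rel
            if not path.exists() or _sha256(path) != digest:
                return False
        return True

    def _record(self, stage: str, inputs_digest: str, outputs: Sequence[Path]) -> None:
        self.manifest[stage] = {
            "complete": True,
            "inputs_digest": inputs_digest,
            "config": self.config.to_dict(),
            "outputs": {
                str(p.relative_to(self.out_dir)): _sha256(p) for p in outputs
            },
        }
        self._save_manifest()

    # -- stage inputs -------------------------------------------------------

    def _stage_input_files(self, stage: str) -> list[Path]:
        d = self.input_dir
        if stage == "families":
            return sorted((d / "proteins").glob("*.faa")) + (
                sorted((d / "assemblies").glob("*.fna")) if self.rescue else []
            )
        if stage in ("pancore", "hostcore"):
            deps = [self.out_dir / "families" / "presence.tsv"]
            if stage == "hostcore":
                deps.append(d / "hosts.tsv")
                if (d / "annotations.tsv").exists():
                    deps.append(d / "annotations.tsv")
            return [p for p in deps if p.exists()]
        if stage == "ani":
            return sorted((d / "assemblies").glob("*.fna"))
        if stage == "aai":
            return sorted((d / "proteins").glob("*.faa"))
        if stage == "treestats":
            return [d / "tree.nwk", d / "hosts.tsv"]
        raise ValueError(f"unknown stage {stage!r}")

    def _check_inputs(self, stages: Sequence[str]) -> None:
        required: dict[str, list[Path]] = {
            "families": [self.input_dir / "proteins"],
            "pancore": [self.input_dir / "proteins"],
            "hostcore": [self.input_dir / "proteins", self.input_dir / "hosts.tsv"],
            "ani": [self.input_dir / "assemblies"],
            "aai": [self.input_dir / "proteins"],
            "treestats": [self.input_dir / "tree.nwk", self.input_dir / "hosts.tsv"],
        }
        missing = [
            str(p) for s in stages for p in required[s] if not p.exists()
        ]
        if missing:
            raise InvalidInputError(
                "missing inputs for requested stages: " + ", ".join(sorted(set(missing)))
            )

    # -- stages -------------------------------------------------------------

    def _run_families(self) -> list[Path]:
        out = self.out_dir / "families"
        out.mkdir(parents=True, exist_ok=True)
        genomes = read_genome_set(self.input_dir / "proteins", protein_suffix=".faa")
        genes = [g for genome in genomes for g in genome.genes]
        logger.info("families: %d genomes, %d genes", len(genomes), len(genes))
        family_set = families.build_families(
            genes,
            identity_threshold=self.config.family_identity_pct,
            coverage_threshold=self.config.family_coverage,
            linkage=self.config.linkage,
        )
        matrix = families.presence_matrix(family_set, genes)
        if self.rescue:
            assemblies = {
                g.genome_id: g.contigs
                for g in read_genome_set(self.input_dir / "assemblies")
            }
            matrix = families.rescue_missing_members(
                family_set, matrix, assemblies, genes,
                identity_threshold=self.config.family_identity_pct,
                coverage_threshold=self.config.family_coverage,
            )
        logger.info("families: %d families", len(family_set))
        families.families_to_tsv(family_set, genes, out / "families.tsv")
        matrix.to_tsv(out / "presence.tsv")
        return [out / "families.tsv", out / "presence.tsv"]

    def _run_pancore(self) -> list[Path]:
        out = self.out_dir / "pancore"
        out.mkdir(parents=True, exist_ok=True)
        matrix = PresenceAbsenceMatrix.from_tsv(self.out_dir / "families" / "presence.tsv")
        curve = pancore.accumulation_curves(
            matrix, n_permutations=self.config.permutations, seed=self.config.seed
        )
        pancore.curve_to_frame(curve).to_csv(out / "curves.csv", index=False)
        fits = {}
        for name, series in (("pan", curve.pan_mean), ("core", curve.core_mean)):
            try:
                fit = pancore.fit_power(curve.n, series)
                fits[name] = dataclasses.asdict(fit)
            except ValueError:
                fits[name] = None
        payload = {
            "core_size": len(pancore.core_families(matrix)),
            "pan_size": len(matrix.family_ids),
            "new_per_genome_mean": curve.new_per_genome_mean,
            "exhaustive": curve.exhaustive,
            "fits": fits,
            "config": self.config.to_dict(),
        }
        (out / "summary.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
        return [out / "curves.csv", out / "summary.json"]

    def _pairwise(self, kind: str) -> list[Path]:
        out = self.out_dir / kind
        out.mkdir(parents=True, exist_ok=True)
        detail: dict[str, dict] = {}
        values: dict[tuple[str, str], float] = {}
        if kind == "ani":
            genomes = read_genome_set(self.input_dir / "assemblies")
            items = {g.genome_id: g.contigs for g in genomes}
        else:
            genomes = read_genome_set(self.input_dir / "proteins", protein_suffix=".faa")
            items = {
                g.genome_id: {gene.gene_id: gene.protein for gene in g.genes}
                for g in genomes
            }
        ids = sorted(items)
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                if kind == "ani":
                    res = aniaai.ani(
                        a, items[a], b, items[b],
                        fragment_length=self.config.ani_fragment_length,
                        min_identity_pct=self.config.ani_min_identity_pct,
                        min_coverage=self.config.ani_min_coverage,
                    )
                    values[(a, b)] = res.ani
                else:
                    res = aniaai.aai(
                        a, items[a], b, items[b],
                        min_identity_pct=self.config.aai_min_identity_pct,
                        min_alignment_length=self.config.aai_min_alignment_length,
                        min_coverage=self.config.aai_min_coverage,
                    )
                    values[(a, b)] = res.aai
                detail[f"{a}|{b}"] = dataclasses.asdict(res)
        matrix = aniaai.pairwise_matrix(values, ids)
        matrix.to_csv(out / f"{kind}_matrix.tsv", sep="\t")
        detail["config"] = self.config.to_dict()
        (out / f"{kind}_pairs.json").write_text(json.dumps(detail, indent=1, sort_keys=True))
        return [out / f"{kind}_matrix.tsv", out / f"{kind}_pairs.json"]

    def _run_hostcore(self) -> list[Path]:
        out = self.out_dir / "hostcore"
        out.mkdir(parents=True, exist_ok=True)
        matrix = PresenceAbsenceMatrix.from_tsv(self.out_dir / "families" / "presence.tsv")
        hosts = read_host_table(self.input_dir / "hosts.tsv")
        groups = self.host_groups or sorted(
            {hosts[g] for g in matrix.genome_ids if g in hosts}
        )
        profiles = hostcore.group_core_sets(matrix, hosts, groups)
        venn = hostcore.venn_partition(
            {p.host: p.core_family_ids for p in profiles}
        )
        with open(out / "host_cores.tsv", "w") as fh:
            fh.write("host\tn_genomes\tn_core_families\tfamily_ids\n")
            for p in profiles:
                fh.write(
                    f"{p.host}\t{len(p.genome_ids)}\t{len(p.core_family_ids)}\t"
                    + ",".join(sorted(p.core_family_ids)) + "\n"
                )
        venn_payload = {
            "+".join(sorted(sig)): sorted(fams)
            for sig, fams in venn.regions.items()
        }
        venn_payload["config"] = self.config.to_dict()
        (out / "venn.json").write_text(json.dumps(venn_payload, indent=1, sort_keys=True))
        outputs = [out / "host_cores.tsv", out / "venn.json"]
        annot_path = self.input_dir / "annotations.tsv"
        if annot_path.exists():
            annotations = read_annotation_table(annot_path)
            rows = []
            for p in profiles:
                dist = hostcore.category_distribution(sorted(p.core_family_ids), annotations)
                for letter in sorted(dist.counts):
                    rows.append(
                        {
                            "host": p.host,
                            "category": letter,
                            "count": dist.counts[letter],
                            "percentage": dist.percentages[letter],
                        }
                    )
            pd.DataFrame(rows).to_csv(out / "categories.csv", index=False)
            outputs.append(out / "categories.csv")
        return outputs

    def _run_treestats(self) -> list[Path]:
        out = self.out_dir / "treestats"
        out.mkdir(parents=True, exist_ok=True)
        tree = phylo.read_newick(self.input_dir / "tree.nwk")
        hosts = read_host_table(self.input_dir / "hosts.tsv")
        records = phylo.node_depth_report(tree, hosts)
        with open(out / "node_depths.tsv", "w") as fh:
            fh.write("tip\thost\tnodes_to_mrca\n")
            for r in records:
                fh.write(f"{r.tip_id}\t{r.host or ''}\t{r.nodes_to_mrca}\n")
        a, b = self.compare_hosts
        x = [r.nodes_to_mrca for r in records if r.host == a]
        y = [r.nodes_to_mrca for r in records if r.host == b]
        payload: dict = {"config": self.config.to_dict(), "compare": [a, b]}
        if x and y:
            res = phylo.wilcoxon_rank_sum(x, y)
            payload["wilcoxon"] = dataclasses.asdict(res)
        (out / "wilcoxon.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
        return [out / "node_depths.tsv", out / "wilcoxon.json"]

    # -- driver -------------------------------------------------------------

    def run(self, stages: Optional[Sequence[str]] = None, force: bool = False) -> dict:
        stages = list(stages) if stages else list(STAGES)
        unknown = [s for s in stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        stages = [s for s in STAGES if s in stages]
        self._check_inputs(stages)
        self.out_dir.mkdir(parents=True, exist_ok=True)
        (self.out_dir / "run_config.yaml").write_text(
            yaml.safe_dump(self.config.to_dict(), sort_keys=True)
        )
        self._load_manifest()
        runners = {
            "families": self._run_families,
            "pancore": self._run_pancore,
            "ani": self._pairwise_ani,
            "aai": self._pairwise_aai,
            "hostcore": self._run_hostcore,
            "treestats": self._run_treestats,
        }
        invalidated: set[str] = set()
        executed: list[str] = []
        for stage in stages:
            inputs = [p for p in self._stage_input_files(stage) if p.exists()]
            digest = _digest_paths(inputs)
            if not force and stage not in invalidated and self._stage_current(stage, digest):
                logger.info("%s: up to date, skipping", stage)
                continue
            logger.info("%s: running", stage)
            outputs = runners[stage]()
            # Inputs may include this run's fresh upstream outputs; re-digest.
            digest = _digest_paths([p for p in self._stage_input_files(stage) if p.exists()])
            self._record(stage, digest, outputs)
            executed.append(stage)
            invalidated.update(_DOWNSTREAM[stage])
        return {"executed": executed, "manifest": self.manifest}

    def _pairwise_ani(self) -> list[Path]:
        return self._pairwise("ani")

    def _pairwise_aai(self) -> list[Path]:
        return self._pairwise("aai")


def run_pipeline(
    config: RunConfig,
    input_dir: str | Path,
    out_dir: str | Path,
    stages: Optional[Sequence[str]] = None,
    force: bool = False,
    **kwargs,
) -> dict:
    return Pipeline(config, input_dir, out_dir, **kwargs).run(stages=stages, force=force)
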