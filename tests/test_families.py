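import numpy as np
import pytest

from bactopan.families import (
    build_families,
    homology_pair_verdict,
    presence_matrix,
    rescue_missing_members,
    select_representative,
)
from bactopan.io import GeneRecord, InvalidInputError

from _oracles import brute_force_partition, pairwise_f1

_AA = "ARNDCQEGHILKMFPSTWYV"


def _gene(gene_id, protein, genome="g1"):
    return GeneRecord(gene_id, genome, protein)


def _random_protein(rng, n):
    return "".join(_AA[i] for i in rng.integers(0, 20, n))


def _mutant(rng, protein, n_subs):
    chars = list(protein)
    for pos in rng.choice(len(chars), size=min(n_subs, len(chars)), replace=False):
        chars[pos] = _AA[rng.integers(0, 20)]
    return "".join(chars)


class TestHomologyPairVerdict:
    def test_identical_proteins(self):
        rng = np.random.default_rng(0)
        p = _random_protein(rng, 100)
        v = homology_pair_verdict(_gene("a", p), _gene("b", p))
        assert v.identity_pct == 100.0
        assert v.longer_gene_coverage == 1.0
        assert v.same_family

    def test_short_perfect_match_fails_longer_coverage(self):
        rng = np.random.default_rng(1)
        long = _random_protein(rng, 300)
        short = long[100:200]  # perfect 100-aa segment of a 300-aa protein
        v = homology_pair_verdict(_gene("short", short), _gene("long", long))
        assert v.identity_pct == 100.0
        assert v.longer_gene_coverage == pytest.approx(100 / 300, abs=0.02)
        assert not v.same_family

    def test_identity_boundary_is_strict(self):
        # identity exactly at the threshold must NOT qualify ("above 50%")
        rng = np.random.default_rng(2)
        p = _random_protein(rng, 100)
        v = homology_pair_verdict(_gene("a", p), _gene("b", p), identity_threshold=100.0)
        assert v.identity_pct == 100.0
        assert not v.same_family

    def test_missing_protein_rejected(self):
        with pytest.raises(ValueError):
            homology_pair_verdict(_gene("a", ""), _gene("b", "MKT"))


class TestBuildFamilies:
    def test_two_identical_genes_one_family(self):
        rng = np.random.default_rng(3)
        p = _random_protein(rng, 80)
        fs = build_families([_gene("a", p), _gene("b", p)])
        assert len(fs) == 1
        assert sorted(fs.families[0].member_ids) == ["a", "b"]

    def test_single_linkage_transitivity(self):
        # A-B and B-C homologous, A-C not: single linkage joins all three.
        rng = np.random.default_rng(4)
        b = _random_protein(rng, 120)
        a = _mutant(rng, b, 40)   # ~66% identity to b
        c = _mutant(rng, b, 40)
        fs = build_families([_gene("A", a), _gene("B", b), _gene("C", c)])
        assert len(fs) == 1
        assert sorted(fs.families[0].member_ids) == ["A", "B", "C"]

    def test_duplicate_ids_rejected(self):
        p = "MKTAYIAKQRQISFVKSHFSRQ"
        with pytest.raises(InvalidInputError):
            build_families([_gene("a", p), _gene("a", p)])

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidInputError):
            build_families([])

    def test_matches_brute_force_components(self):
        rng = np.random.default_rng(5)
        genes = []
        for fam in range(6):
            base = _random_protein(rng, int(rng.integers(40, 90)))
            for copy in range(int(rng.integers(1, 5))):
                genes.append(
                    _gene(f"f{fam}c{copy}", _mutant(rng, base, int(rng.integers(0, 10))))
                )
        fs = build_families(genes)
        from bactopan.families import homology_pair_verdict as verdict
        by_id = {g.gene_id: g for g in genes}
        expected = brute_force_partition(
            [g.gene_id for g in genes],
            lambda x, y: verdict(by_id[x], by_id[y]).same_family,
        )
        ours = {frozenset(f.member_ids) for f in fs.families}
        assert ours == expected

    def test_prefilter_lossless_on_random_instances(self):
        rng = np.random.default_rng(6)
        genes = []
        for fam in range(5):
            base = _random_protein(rng, int(rng.integers(35, 70)))
            for copy in range(int(rng.integers(1, 4))):
                genes.append(
                    _gene(f"f{fam}c{copy}", _mutant(rng, base, int(rng.integers(0, 8))))
                )
        fast = build_families(genes, prefilter=True)
        exact = build_families(genes, prefilter=False)
        assert {frozenset(f.member_ids) for f in fast.families} == {
            frozenset(f.member_ids) for f in exact.families
        }

    def test_partition_property(self, small_simulation_genes):
        fs = build_families(small_simulation_genes)
        total = sum(len(f.member_ids) for f in fs.families)
        assert total == len(small_simulation_genes)
        seen = set()
        for f in fs.families:
            for m in f.member_ids:
                assert m not in seen
                seen.add(m)

    def test_recovers_simulated_truth(self, small_simulation, small_simulation_genes):
        fs = build_families(small_simulation_genes)
        predicted = {frozenset(f.member_ids) for f in fs.families}
        truth_groups: dict[str, set] = {}
        for gene, fam in small_simulation.truth.gene_to_family.items():
            truth_groups.setdefault(fam, set()).add(gene)
        truth = {frozenset(v) for v in truth_groups.values()}
        assert pairwise_f1(predicted, truth) >= 0.95

    def test_complete_linkage_is_finer_or_equal(self):
        rng = np.random.default_rng(7)
        base = _random_protein(rng, 100)
        genes = [_gene(f"g{i}", _mutant(rng, base, 35)) for i in range(5)]
        single = build_families(genes, linkage="single")
        complete = build_families(genes, linkage="complete")
        assert len(complete) >= len(single)


class TestSelectRepresentative:
    def test_longest_member_wins(self):
        genes = [_gene("g1", "M" * 300), _gene("g2", "M" * 250)]
        assert select_representative(genes) == "g1"

    def test_tie_breaks_to_smallest_id(self):
        genes = [_gene("gX", "K" * 250), _gene("gA", "R" * 250)]
        assert select_representative(genes) == "gA"

    def test_singleton(self):
        assert select_representative([_gene("only", "MKT")]) == "only"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_representative([])


class TestRescue:
    def _setup(self, drop_from_genome2: bool):
        rng = np.random.default_rng(8)
        protein = _random_protein(rng, 90)
        from bactopan.simulate import _SENSE_CODONS  # reuse codon table

        codon_of = {}
        from Bio.Seq import Seq
        for codon in ("".join("ACGT"[b] for b in c) for c in _SENSE_CODONS):
            codon_of.setdefault(str(Seq(codon).translate(table=11)), codon)
        cds = "".join(codon_of[aa] for aa in protein)
        spacer = "".join("ACGT"[i] for i in rng.integers(0, 4, 150))
        genomes = {
            "g1": {"g1_chr": spacer + cds + spacer},
            "g2": {"g2_chr": spacer + cds + spacer},
        }
        genes = [GeneRecord("gene1", "g1", protein, cds)]
        if not drop_from_genome2:
            genes.append(GeneRecord("gene2", "g2", protein, cds))
        fs = build_families(genes)
        matrix = presence_matrix(fs, genes)
        if drop_from_genome2:
            # presence matrix lacks g2 entirely; add the column as absent
            df = matrix.df.copy()
            df["g2"] = False
            from bactopan.pancore import PresenceAbsenceMatrix
            matrix = PresenceAbsenceMatrix(df)
        return fs, matrix, genomes, genes

    def test_unannotated_orf_rescued(self):
        fs, matrix, genomes, genes = self._setup(drop_from_genome2=True)
        updated = rescue_missing_members(fs, matrix, genomes, genes)
        assert bool(updated.df.iloc[0]["g2"])

    def test_no_similarity_stays_absent(self):
        fs, matrix, genomes, genes = self._setup(drop_from_genome2=True)
        rng = np.random.default_rng(9)
        genomes["g2"] = {"g2_chr": "".join("ACGT"[i] for i in rng.integers(0, 4, 600))}
        updated = rescue_missing_members(fs, matrix, genomes, genes)
        assert not bool(updated.df.iloc[0]["g2"])

    def test_idempotent_on_complete_annotation(self):
        fs, matrix, genomes, genes = self._setup(drop_from_genome2=False)
        updated = rescue_missing_members(fs, matrix, genomes, genes)
        assert updated.df.equals(matrix.df)

    def test_presence_monotone(self, small_simulation, small_simulation_genes):
        fs = build_families(small_simulation_genes)
        matrix = presence_matrix(fs, small_simulation_genes)
        contigs = {g: sim.contigs for g, sim in small_simulation.genomes.items()}
        updated = rescue_missing_members(fs, matrix, contigs, small_simulation_genes)
        before = matrix.df.to_numpy()
        after = updated.df.to_numpy()
        assert (after | before).sum() == after.sum()  # only flips absences
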