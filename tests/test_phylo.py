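import itertools

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from bactopan.phylo import (
    NewickParseError,
    NotMonophyleticError,
    bipartitions,
    concatenate_alignments,
    node_depth_report,
    nodes_to_mrca,
    parse_newick,
    root_with_outgroup,
    wilcoxon_rank_sum,
)
from bactopan.simulate import simulate_tree

from _oracles import rank_sum_exact


class TestParseNewick:
    def test_cherry(self):
        tree = parse_newick("(A,B);")
        assert tree.tip_labels() == ["A", "B"]
        assert len(tree.internal_nodes()) == 1

    def test_internal_support_label_preserved(self):
        tree = parse_newick("((A:1,B:2)90:0.5,C:3);")
        internal = [n for n in tree.internal_nodes() if n.name == "90"]
        assert len(internal) == 1
        assert internal[0].length == 0.5
        assert tree.find_tip("B").length == 2.0

    def test_quoted_labels(self):
        tree = parse_newick("('taxon A','don''t panic');")
        assert tree.tip_labels() == ["taxon A", "don't panic"]

    def test_malformed_reports_offset(self):
        with pytest.raises(NewickParseError) as err:
            parse_newick("((A,B)")
        assert err.value.offset == 6

    def test_missing_semicolon(self):
        with pytest.raises(NewickParseError):
            parse_newick("(A,B)")

    def test_round_trip_idempotent_on_random_trees(self):
        for seed in range(100):
            tree = simulate_tree(n_tips=int(3 + seed % 10), seed=seed)
            once = parse_newick(tree.to_newick()).to_newick()
            twice = parse_newick(once).to_newick()
            assert once == twice

    def test_round_trip_preserves_topology(self):
        text = "((A:1,B:2)90:0.5,(C:0.1,D:0.2)75:0.3);"
        tree = parse_newick(text)
        again = parse_newick(tree.to_newick())
        assert again.tip_labels() == tree.tip_labels()
        assert bipartitions(again) == bipartitions(tree)


class TestRootWithOutgroup:
    def test_simple_reroot(self):
        tree = parse_newick("((A,B),(C,D));")
        rooted = root_with_outgroup(tree, ["D"])
        # outgroup-first child order: first child is D, second the ingroup
        assert rooted.root.children[0].name == "D"
        ingroup_tips = {t.name for t in rooted.tips()} - {"D"}
        assert ingroup_tips == {"A", "B", "C"}

    def test_all_tips_outgroup_rejected(self):
        tree = parse_newick("((A,B),(C,D));")
        with pytest.raises(NotMonophyleticError):
            root_with_outgroup(tree, ["A", "B", "C", "D"])

    def test_non_monophyletic_rejected(self):
        tree = parse_newick("((A,B),(C,D));")
        with pytest.raises(NotMonophyleticError):
            root_with_outgroup(tree, ["A", "C"])

    def test_rerooting_preserves_bipartitions(self):
        for seed in range(20):
            tree = simulate_tree(n_tips=8, seed=seed)
            tips = tree.tip_labels()
            rooted = root_with_outgroup(tree, [tips[seed % len(tips)]])
            assert bipartitions(rooted) == bipartitions(tree)
            assert sorted(rooted.tip_labels()) == sorted(tips)

    def test_outgroup_clade(self):
        tree = parse_newick("(((A,B),C),(X,Y));")
        rooted = root_with_outgroup(tree, ["X", "Y"])
        first = rooted.root.children[0]
        assert {t for t in _tip_names(first)} == {"X", "Y"}


def _tip_names(node):
    if not node.children:
        return {node.name}
    out = set()
    for c in node.children:
        out |= _tip_names(c)
    return out


class TestNodesToMRCA:
    def test_cherry_convention(self):
        tree = parse_newick("(A,B);")
        assert nodes_to_mrca(tree, "A") == 1
        assert nodes_to_mrca(tree, "B") == 1

    def test_three_tips(self):
        tree = parse_newick("((A,B),C);")
        assert nodes_to_mrca(tree, "A") == 2
        assert nodes_to_mrca(tree, "B") == 2
        assert nodes_to_mrca(tree, "C") == 1

    def test_caterpillar(self):
        tree = parse_newick("((((A,B),C),D),E);")
        assert nodes_to_mrca(tree, "A") == 4
        assert nodes_to_mrca(tree, "E") == 1

    def test_unknown_tip_rejected(self):
        tree = parse_newick("(A,B);")
        with pytest.raises(ValueError):
            nodes_to_mrca(tree, "Z")

    def test_branch_length_invariance(self):
        bare = parse_newick("((((A,B),C),D),E);")
        lengthy = parse_newick("((((A:9,B:0.01):5,C:2):0.1,D:7):3,E:0.5);")
        for tip in "ABCDE":
            assert nodes_to_mrca(bare, tip) == nodes_to_mrca(lengthy, tip)

    def test_max_depth_bounded_by_internal_count(self):
        for seed in range(10):
            tree = simulate_tree(n_tips=12, seed=seed)
            n_internal = len(tree.internal_nodes())
            assert max(nodes_to_mrca(tree, t) for t in tree.tip_labels()) <= n_internal

    def test_report_carries_hosts(self):
        tree = parse_newick("((A,B),C);")
        records = node_depth_report(tree, {"A": "bee", "C": "human"})
        by_tip = {r.tip_id: r for r in records}
        assert by_tip["A"].host == "bee"
        assert by_tip["B"].host is None
        assert by_tip["C"].nodes_to_mrca == 1


class TestWilcoxonRankSum:
    def test_fully_separated_one_sided(self):
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], alternative="less", method="exact")
        assert res.p_value == pytest.approx(1 / 20)
        assert res.method == "exact"

    def test_tied_two_sided(self):
        res = wilcoxon_rank_sum([1, 1], [2, 2], alternative="two-sided", method="exact")
        assert res.p_value == pytest.approx(1 / 3)

    def test_identical_samples(self):
        res = wilcoxon_rank_sum([5, 5, 5], [5, 5, 5], method="exact")
        assert res.p_value == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    def test_exact_matches_enumeration_all_small_splits(self):
        rng = np.random.default_rng(21)
        for total in range(2, 13):
            for nx in range(1, total):
                values = rng.integers(0, 6, size=total).astype(float)  # ties likely
                x, y = list(values[:nx]), list(values[nx:])
                for alternative in ("two-sided", "less", "greater"):
                    ours = wilcoxon_rank_sum(x, y, alternative, method="exact")
                    assert ours.p_value == pytest.approx(
                        rank_sum_exact(x, y, alternative)
                    ), (total, nx, alternative)

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(22)
        x = list(rng.permutation(20)[:8].astype(float))
        y = list(rng.permutation(40)[20:29].astype(float) + 0.5)
        ours = wilcoxon_rank_sum(x, y, "two-sided", method="exact")
        ref = mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_normal_close_to_exact_at_total_20(self):
        rng = np.random.default_rng(23)
        values = rng.permutation(100)[:20].astype(float)  # no ties
        x, y = list(values[:9]), list(values[9:])
        exact = wilcoxon_rank_sum(x, y, "two-sided", method="exact")
        approx = wilcoxon_rank_sum(x, y, "two-sided", method="normal")
        assert abs(exact.p_value - approx.p_value) < 0.01

    def test_auto_switches_to_normal(self):
        x = list(range(15))
        y = list(range(7, 22))
        res = wilcoxon_rank_sum(x, y)
        assert res.method == "normal-approximation"


class TestConcatenateAlignments:
    def test_widths_and_partitions(self):
        blocks = {
            "f1": {"g1": "A" * 10, "g2": "C" * 10, "g3": "G" * 10},
            "f2": {"g1": "M" * 20, "g2": "K" * 20, "g3": "R" * 20},
        }
        matrix, parts = concatenate_alignments(blocks)
        assert all(len(s) == 30 for s in matrix.values())
        assert parts == [("f1", 1, 10), ("f2", 11, 30)]

    def test_missing_genome_gap_padded(self):
        blocks = {
            "f1": {"g1": "AAAA", "g2": "CCCC"},
            "f2": {"g1": "MM"},
        }
        matrix, _ = concatenate_alignments(blocks)
        assert matrix["g2"] == "CCCC--"

    def test_ragged_block_rejected(self):
        with pytest.raises(ValueError):
            concatenate_alignments({"f1": {"g1": "AA", "g2": "AAA"}})

    def test_total_width_is_sum_of_blocks(self):
        rng = np.random.default_rng(24)
        blocks = {}
        for i in range(50):
            width = int(rng.integers(1, 30))
            blocks[f"f{i:02d}"] = {
                g: "A" * width for g in ("g1", "g2") if rng.random() < 0.9
            } or {"g1": "A" * width}
        matrix, parts = concatenate_alignments(blocks)
        total = sum(end - start + 1 for _, start, end in parts)
        assert all(len(s) == total for s in matrix.values())


def test_tree_path_length():
    tree = parse_newick("((A:1,B:2):0.5,C:3);")
    assert tree.path_length("A", "B") == pytest.approx(3.0)
    assert tree.path_length("A", "C") == pytest.approx(4.5)
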