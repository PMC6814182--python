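"""NJ/JC round trips, consensus and bootstrap, shrinking, conflict counts."""

import warnings

import dendropy
import numpy as np
import pytest

from hybcurate import SimConfig, generate_taxonomy, simulate_alignment, \
    simulate_gene_trees
from hybcurate.alignments import LocusAlignment
from hybcurate.trees import (bootstrap_support, collapse_low_support,
                             conflict_analysis, detect_long_branches,
                             jc_distance, majority_consensus_tree,
                             nj_from_matrix, nj_tree, p_distance,
                             shrink_dataset, unrooted_splits)

from conftest import make_alignment, rooted_tree


class TestDistances:
    def test_pairwise_deletion(self):
        p, n = p_distance("ACGTNN", "ACTT-A")
        assert n == 4 and p == pytest.approx(1 / 4)

    def test_saturated_pair_capped_with_warning(self):
        with pytest.warns(UserWarning, match="saturation"):
            assert jc_distance(0.76, max_distance=5.0) == 5.0

    def test_zero_comparable_sites_rejected(self):
        aln = make_alignment(a="NNNN", b="ACGT", c="ACGT")
        with pytest.raises(ValueError, match="comparable"):
            nj_tree(aln)


class TestNeighborJoining:
    def test_additive_matrix_recovered_exactly(self):
        labels = ["a", "b", "c", "d"]
        m = np.array([[0, 3, 7, 8], [3, 0, 6, 7],
                      [7, 6, 0, 3], [8, 7, 3, 0]], dtype=float)
        tree = nj_from_matrix(labels, m)
        assert unrooted_splits(tree) == {frozenset({"c", "d"})}
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for i, x in enumerate(labels):
            for j, y in enumerate(labels):
                if i < j:
                    assert pdm.patristic_distance(
                        taxa[x], taxa[y]) == pytest.approx(m[i, j])

    def test_three_taxa(self):
        aln = make_alignment(a="AAAA", b="AAAC", c="AACC")
        tree = nj_tree(aln)
        assert len(tree.leaf_nodes()) == 3
        assert unrooted_splits(tree) == set()

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(make_alignment(a="ACGT", b="ACGT"))

    def test_recovers_true_gene_tree_topology(self):
        cfg = SimConfig(n_tribes=2, genera_per_tribe=1, species_per_genus=3,
                        samples_per_species=1, n_loci=1, subst_scale=0.2,
                        discordance_rate=0, long_branch_rate=0, seed=13)
        _, sp = generate_taxonomy(cfg)
        gts, _ = simulate_gene_trees(sp, cfg)
        aln = simulate_alignment(gts["L0001"], 5000, 0.2, seed=[13, 0])
        assert unrooted_splits(nj_tree(aln)) == unrooted_splits(gts["L0001"])


class TestBootstrap:
    def test_unanimous_signal_full_support(self):
        aln = make_alignment(A="AAAA", B="AAAA", C="CCCC", D="CCCC")
        tree = bootstrap_support(aln, n_reps=25, seed=0)
        supports = [n.support for n in
                    tree.preorder_internal_node_iter(exclude_seed_node=True)
                    if hasattr(n, "support")]
        assert supports and all(s == 100.0 for s in supports)

    def test_deterministic_given_seed(self):
        aln = make_alignment(A="ACCA" * 5, B="ACTA" * 5, C="GCTG" * 5,
                             D="GTTG" * 5, E="GTAG" * 5)
        t1 = bootstrap_support(aln, 20, seed=7)
        t2 = bootstrap_support(aln, 20, seed=7)
        s1 = sorted(n.support for n in t1 if hasattr(n, "support"))
        s2 = sorted(n.support for n in t2 if hasattr(n, "support"))
        assert s1 == s2

    def test_conflicting_patterns_near_half_support(self):
        # equally frequent AB|CD and AC|BD column patterns
        col_ab = {"A": "A", "B": "A", "C": "C", "D": "C"}
        col_ac = {"A": "A", "B": "C", "C": "A", "D": "C"}
        const = {s: "G" for s in "ABCD"}
        n = 400
        cols = [col_ab if i % 4 == 0 else col_ac if i % 4 == 1 else const
                for i in range(n)]
        seqs = {s: "".join(c[s] for c in cols) for s in "ABCD"}
        tree = bootstrap_support(LocusAlignment("L", seqs), 200, seed=3)
        supports = [nd.support for nd in
                    tree.preorder_internal_node_iter(exclude_seed_node=True)
                    if hasattr(nd, "support")]
        assert supports and 35 <= supports[0] <= 65

    def test_invalid_reps(self):
        with pytest.raises(ValueError):
            bootstrap_support(make_alignment(a="A", b="A", c="A"), 0, seed=0)


class TestConsensusTree:
    def test_identical_trees(self):
        trees = [rooted_tree("((a,b),(c,d));") for _ in range(10)]
        cons = majority_consensus_tree(trees)
        assert unrooted_splits(cons) == {frozenset({"c", "d"})}
        supports = [n.support for n in cons if getattr(n, "support", None)]
        assert all(s == 100.0 for s in supports)

    def test_majority_split_with_occurrence_support(self):
        trees = ([rooted_tree("((A,B),(C,D));") for _ in range(6)]
                 + [rooted_tree("((A,C),(B,D));") for _ in range(4)])
        cons = majority_consensus_tree(trees)
        assert unrooted_splits(cons) == {frozenset({"C", "D"})}
        node = next(n for n in cons if getattr(n, "support", None))
        assert node.support == pytest.approx(60.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            majority_consensus_tree([])


class TestLongBranchDetection:
    def _trees(self, cfg):
        _, sp = generate_taxonomy(cfg)
        return simulate_gene_trees(sp, cfg)

    def test_clean_trees_nothing_flagged_below_min_signature(self):
        cfg = SimConfig(n_tribes=2, genera_per_tribe=2, species_per_genus=2,
                        samples_per_species=1, n_loci=50, discordance_rate=0,
                        long_branch_rate=0, seed=1)
        gts, _ = self._trees(cfg)
        report = detect_long_branches(gts, tolerance=0.10, min_signature=0.2)
        assert report.n_flagged == 0

    def test_planted_outliers_recovered(self):
        cfg = SimConfig(n_tribes=2, genera_per_tribe=2, species_per_genus=2,
                        samples_per_species=1, n_loci=100, discordance_rate=0,
                        long_branch_rate=0.2, long_branch_factor=10, seed=2)
        gts, truth = self._trees(cfg)
        report = detect_long_branches(gts, tolerance=0.10)
        planted = {(l, s) for l, s, _ in truth.inflated_leaves}
        flagged = {(l, s) for l, ss in report.removed.items() for s in ss}
        assert len(flagged & planted) / len(planted) >= 0.9

    def test_small_trees_skipped_with_warning(self):
        tiny = {"L1": rooted_tree("((a:1,b:1):1,c:1);")}
        with pytest.warns(UserWarning, match="<4 leaves"):
            report = detect_long_branches(tiny)
        assert report.removed == {}

    def test_invalid_tolerance(self):
        with pytest.raises(ValueError):
            detect_long_branches({}, tolerance=0.0)


class TestShrinkDataset:
    def _alignments(self, n=10):
        return {f"L{i}": make_alignment(f"L{i}", a="ACGT", b="ACGT",
                                        c="ACGT", d="ACGT")
                for i in range(n)}

    def test_empty_report_noop(self):
        from hybcurate.trees import ShrinkReport
        alns = self._alignments()
        out, frac = shrink_dataset(alns, ShrinkReport())
        assert frac == 0.0
        assert {l: a.sequences for l, a in out.items()} == {
            l: a.sequences for l, a in alns.items()}

    def test_fraction_and_removals(self):
        from hybcurate.trees import ShrinkReport
        report = ShrinkReport(removed={"L0": {"a"}, "L3": {"b"}, "L7": {"a"}})
        out, frac = shrink_dataset(self._alignments(), report)
        assert frac == pytest.approx(0.3)
        assert "a" not in out["L0"] and out["L0"].n_samples == 3

    def test_removal_below_min_samples_drops_alignment(self):
        from hybcurate.trees import ShrinkReport
        report = ShrinkReport(removed={"L0": {"a", "b"}})
        with pytest.warns(UserWarning, match="dropped"):
            out, frac = shrink_dataset(self._alignments(1), report)
        assert "L0" not in out and frac == 1.0

    def test_absent_sample_warns_and_noops(self):
        from hybcurate.trees import ShrinkReport
        report = ShrinkReport(removed={"L0": {"zz"}})
        with pytest.warns(UserWarning, match="not in alignment"):
            out, frac = shrink_dataset(self._alignments(1), report)
        assert frac == 0.0 and out["L0"].n_samples == 4


class TestConflictAnalysis:
    def test_direct_count_example(self):
        sp = rooted_tree("((A,B),(C,D));")
        gts = {f"g{i}": rooted_tree("((A,B),(C,D));") for i in range(6)}
        gts |= {f"h{i}": rooted_tree("((A,C),(B,D));") for i in range(3)}
        gts["k"] = rooted_tree("((A,D),(B,C));")
        report = conflict_analysis(sp, gts, bs_threshold=80)
        node = report.nodes[frozenset({"A", "B"})]
        assert (node.concordant, node.top_alternative,
                node.other_conflict, node.uninformative) == (6, 3, 1, 0)
        assert node.top_alternative_clade == frozenset({"A", "C"})

    def test_counts_sum_to_usable_at_every_node(self, small_dataset):
        ds = small_dataset
        outgroup = ds.samples[0]
        sp = ds.species_tree.clone(depth=1)
        og = next(lf for lf in sp.leaf_node_iter()
                  if lf.taxon.label == outgroup)
        sp.to_outgroup_position(og, update_bipartitions=False)
        report = conflict_analysis(sp, ds.gene_trees, 80, outgroup)
        assert report.n_usable == len(ds.gene_trees)
        for node in report.nodes.values():
            assert node.total == report.n_usable

    def test_low_support_everywhere_uninformative(self):
        sp = rooted_tree("((A,B),(C,D));")
        gt = rooted_tree("((A,C)40,(B,D)40);")
        report = conflict_analysis(sp, {"g": gt}, bs_threshold=80)
        for node in report.nodes.values():
            assert node.uninformative == 1 and node.concordant == 0

    def test_missing_outgroup_excluded_and_counted(self):
        sp = rooted_tree("(O,((A,B),(C,D)));")
        gts = {f"g{i}": rooted_tree("(O,((A,B),(C,D)));") for i in range(8)}
        gts |= {f"m{i}": rooted_tree("((A,B),(C,D));") for i in range(2)}
        report = conflict_analysis(sp, gts, 80, outgroup="O")
        assert report.n_usable == 8
        assert report.n_excluded_missing_outgroup == 2
        for node in report.nodes.values():
            assert node.total == 8

    def test_unrooted_species_tree_rejected(self):
        sp = dendropy.Tree.get(data="((A,B),(C,D));", schema="newick")
        sp.is_rooted = False
        with pytest.raises(ValueError):
            conflict_analysis(sp, {}, 80)

    def test_collapse_low_support(self):
        gt = rooted_tree("(((A,B)95,C)40,(D,E)90);")
        collapsed = collapse_low_support(gt, 80)
        clades = {frozenset(lf.taxon.label for lf in n.leaf_iter())
                  for n in collapsed.preorder_internal_node_iter(
                      exclude_seed_node=True)}
        assert frozenset({"A", "B", "C"}) not in clades
        assert frozenset({"A", "B"}) in clades
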