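"""Generator behaviour: taxonomy shape, planted-event bookkeeping,
Jukes-Cantor calibration, and determinism."""

import dendropy
import numpy as np
import pytest
from scipy import stats

from hybcurate import (SimConfig, generate_dataset, generate_taxonomy,
                       simulate_alignment, simulate_gene_trees,
                       simulate_pileup)
from hybcurate.simulate import jc_expected_p
from hybcurate.trees import unrooted_splits


def binom_99(n, p):
    lo, hi = stats.binom.interval(0.99, n, p)
    return int(lo), int(hi)


class TestTaxonomy:
    @pytest.mark.parametrize("counts,n_samples,n_tribes,n_genera,n_species", [
        ((2, 2, 2, 1), 8, 2, 4, 8),
        ((1, 1, 1, 3), 3, 1, 1, 1),
        ((3, 2, 1, 2), 12, 3, 6, 6),
    ])
    def test_counts(self, counts, n_samples, n_tribes, n_genera, n_species):
        nt, gpt, spg, sps = counts
        table, tree = generate_taxonomy(SimConfig(
            n_tribes=nt, genera_per_tribe=gpt, species_per_genus=spg,
            samples_per_species=sps))
        assert len(table) == n_samples
        assert table["tribe"].nunique() == n_tribes
        assert table["genus"].nunique() == n_genera
        assert table["species"].nunique() == n_species
        assert len(tree.leaf_nodes()) == n_samples
        # every sample in exactly one group per level
        assert table["sample"].is_unique

    def test_ultrametric_and_binary(self):
        _, tree = generate_taxonomy(SimConfig(n_tribes=3, genera_per_tribe=2))
        depths = {lf.taxon.label: lf.distance_from_root()
                  for lf in tree.leaf_node_iter()}
        assert np.allclose(list(depths.values()), 1.0)
        for node in tree.preorder_node_iter():
            assert node.is_leaf() or len(node.child_nodes()) == 2

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_tribes=0)

    def test_same_seed_identical(self):
        a = generate_dataset(SimConfig(seed=9, n_loci=5, locus_length=50,
                                       dropout_prob=0.2, partial_prob=0.2))
        b = generate_dataset(SimConfig(seed=9, n_loci=5, locus_length=50,
                                       dropout_prob=0.2, partial_prob=0.2))
        assert a.sample_table.equals(b.sample_table)
        for locus in a.alignments:
            assert a.alignments[locus].sequences == b.alignments[locus].sequences
        assert a.contigs.equals(b.contigs)
        assert a.truth.masked_cells == b.truth.masked_cells
        assert a.truth.discordant_loci == b.truth.discordant_loci


class TestGeneTrees:
    def test_zero_discordance_preserves_topology(self):
        cfg = SimConfig(discordance_rate=0.0, long_branch_rate=0.0, n_loci=10)
        _, sp = generate_taxonomy(cfg)
        gts, truth = simulate_gene_trees(sp, cfg)
        ref = unrooted_splits(sp)
        assert all(unrooted_splits(t) == ref for t in gts.values())
        assert truth.discordant_loci == set()

    def test_discordant_trees_differ_and_rate_within_binomial(self):
        cfg = SimConfig(discordance_rate=0.2, long_branch_rate=0.0,
                        n_loci=100, seed=17)
        _, sp = generate_taxonomy(cfg)
        gts, truth = simulate_gene_trees(sp, cfg)
        ref = unrooted_splits(sp)
        for locus in truth.discordant_loci:
            assert unrooted_splits(gts[locus]) != ref
        lo, hi = binom_99(100, 0.2)
        assert lo <= len(truth.discordant_loci) <= hi

    def test_long_branch_inflation_factor(self):
        cfg = SimConfig(discordance_rate=0.0, long_branch_rate=1.0,
                        long_branch_factor=10.0, n_loci=5, seed=3)
        _, sp = generate_taxonomy(cfg)
        base = {lf.taxon.label: lf.edge.length for lf in sp.leaf_node_iter()}
        gts, truth = simulate_gene_trees(sp, cfg)
        assert len(truth.inflated_leaves) == 5
        for locus, sample, factor in truth.inflated_leaves:
            leaf = next(lf for lf in gts[locus].leaf_node_iter()
                        if lf.taxon.label == sample)
            assert leaf.edge.length == pytest.approx(base[sample] * factor)

    def test_nonbinary_species_tree_rejected(self):
        tri = dendropy.Tree.get(data="(a:1,b:1,c:1,d:1);", schema="newick")
        tri.is_rooted = True
        with pytest.raises(ValueError):
            simulate_gene_trees(tri, SimConfig())


class TestSequenceEvolution:
    def test_zero_branch_lengths_identical_sequences(self):
        tree = dendropy.Tree.get(data="((a:0,b:0):0,(c:0,d:0):0);",
                                 schema="newick")
        aln = simulate_alignment(tree, 100, 1.0, seed=1)
        seqs = set(aln.sequences.values())
        assert len(seqs) == 1

    def test_jc_p_distance_matches_closed_form(self):
        # two leaves at total path distance 0.1; expected p ~ 0.0928
        tree = dendropy.Tree.get(data="(a:0.05,b:0.05);", schema="newick")
        aln = simulate_alignment(tree, 10_000, 1.0, seed=2)
        a, b = aln["a"], aln["b"]
        p = sum(x != y for x, y in zip(a, b)) / len(a)
        assert p == pytest.approx(jc_expected_p(0.1), abs=0.01)

    def test_alignment_shape_and_alphabet(self):
        tree = dendropy.Tree.get(data="((a:0.1,b:0.1):0.1,c:0.2);",
                                 schema="newick")
        aln = simulate_alignment(tree, 250, 1.0, seed=3)
        assert all(len(s) == 250 for s in aln.sequences.values())
        assert set("".join(aln.sequences.values())) <= set("ACGT")

    def test_zero_length_rejected(self):
        tree = dendropy.Tree.get(data="(a:0.1,b:0.1);", schema="newick")
        with pytest.raises(ValueError):
            simulate_alignment(tree, 0, 1.0, seed=1)


class TestPileups:
    def test_error_free_pileup_modal_base_is_truth(self):
        counts = simulate_pileup("ACGT" * 25, 30.0, 0.0, seed=4)
        lut = {b: i for i, b in enumerate("ACGT")}
        truth = "ACGT" * 25
        for pos in range(100):
            if counts[pos].sum() > 0:
                assert counts[pos].argmax() == lut[truth[pos]]
                assert counts[pos].sum() == counts[pos, lut[truth[pos]]]

    def test_zero_coverage(self):
        counts = simulate_pileup("ACGT", 0.0, 0.1, seed=5)
        assert counts.sum() == 0

    def test_error_fraction_within_binomial(self):
        counts = simulate_pileup("A" * 2000, 50.0, 0.02, seed=6)
        total = counts.sum()
        errors = total - counts[:, 0].sum()
        lo, hi = binom_99(int(total), 0.02)
        assert lo <= errors <= hi

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            simulate_pileup("ACGT", -1.0, 0.0, seed=1)
        with pytest.raises(ValueError):
            simulate_pileup("ACGT", 5.0, 1.0, seed=1)


class TestMissingness:
    def test_dropout_one_removes_everything(self):
        cfg = SimConfig(n_loci=4, locus_length=40, dropout_prob=1.0, seed=7)
        ds = generate_dataset(cfg)
        assert all(a.n_samples == 0 for a in ds.alignments.values())

    def test_no_missingness_leaves_dataset_unchanged(self):
        cfg = SimConfig(n_loci=4, locus_length=40, dropout_prob=0.0,
                        partial_prob=0.0, seed=7)
        ds = generate_dataset(cfg)
        assert ds.truth.masked_cells == set()
        for locus, aln in ds.alignments.items():
            assert aln.sequences == ds.true_sequences[locus]

    def test_partial_masks_single_run_of_expected_length(self):
        cfg = SimConfig(n_loci=6, locus_length=100, dropout_prob=0.0,
                        partial_prob=1.0, partial_fraction=0.3, seed=8)
        ds = generate_dataset(cfg)
        expected = int(np.ceil(0.3 * 100))
        for sample, locus, kind in ds.truth.masked_cells:
            assert kind == "partial"
            seq = ds.alignments[locus][sample]
            assert seq.count("N") == expected
            first, last = seq.index("N"), seq.rindex("N")
            assert last - first + 1 == expected  # one contiguous run

    def test_planted_rates_within_binomial(self):
        cfg = SimConfig(n_tribes=2, genera_per_tribe=2, species_per_genus=2,
                        samples_per_species=2, n_loci=100, locus_length=30,
                        dropout_prob=0.1, partial_prob=0.0, seed=9)
        ds = generate_dataset(cfg)
        n_cells = 16 * 100
        dropped = sum(1 for _, _, k in ds.truth.masked_cells if k == "dropped")
        lo, hi = binom_99(n_cells, 0.1)
        assert lo <= dropped <= hi
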