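import numpy as np
import pytest

from famevo import phylo, synthetic_data as sd
from famevo.expression import classify_de
from famevo.genome_map import detect_tandem
from famevo.phylostrat import classify_presence, stratum_proportions


class TestSimulateTree:
    @pytest.mark.parametrize("n", [2, 3, 5, 17, 50])
    def test_leaf_count(self, n):
        tree = sd.simulate_tree(n, seed=1)
        assert sum(1 for _ in tree.leaf_node_iter()) == n

    def test_deterministic(self):
        a = sd.simulate_tree(5, seed=42).as_string(schema="newick")
        b = sd.simulate_tree(5, seed=42).as_string(schema="newick")
        assert a == b

    def test_two_taxa(self):
        tree = sd.simulate_tree(2, seed=0)
        labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
        assert labels == ["sp1", "sp2"]

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            sd.simulate_tree(1, seed=0)


class TestEvolveSequences:
    def test_zero_branch_lengths_identical(self):
        tree = sd.simulate_tree(4, seed=3)
        for node in tree.preorder_node_iter():
            if node.edge.length is not None:
                node.edge.length = 0.0
        aln = sd.evolve_sequences(tree, 100, seed=4)
        assert len(set(aln.rows)) == 1

    def test_long_branch_saturates_at_19_of_20(self):
        import dendropy

        tree = dendropy.Tree.get(data="(a:500.0,b:0.0);", schema="newick")
        aln = sd.evolve_sequences(tree, 5000, seed=9)
        p = np.mean([c1 != c2 for c1, c2 in zip(*aln.rows)])
        assert p == pytest.approx(19 / 20, abs=0.02)

    def test_nj_recovers_simulated_topology(self):
        """With ample sites, NJ on Poisson distances recovers the
        generating 6-taxon topology in >=95% of seeds."""
        hits = 0
        for seed in range(60):
            tree = sd.simulate_tree(6, seed=seed)
            aln = sd.evolve_sequences(tree, 10_000, seed=seed + 1)
            njt = phylo.nj_tree(phylo.pairwise_distance(aln))
            hits += phylo.tree_splits(njt) == phylo.tree_splits(tree)
        assert hits >= 0.95 * 60

    def test_negative_rate_rejected(self):
        tree = sd.simulate_tree(3, seed=0)
        with pytest.raises(ValueError):
            sd.evolve_sequences(tree, 10, rate=-1.0, seed=0)


class TestSimulateFamilyPair:
    def test_member_counts(self):
        tree = sd.simulate_tree(5, seed=1)
        fam_a, fam_b = sd.simulate_family_pair(tree, 0.5, 4, 2, 50, seed=2)
        assert len(fam_a) == 4 and len(fam_b) == 2

    def test_rho_out_of_range_rejected(self):
        tree = sd.simulate_tree(5, seed=1)
        with pytest.raises(ValueError):
            sd.simulate_family_pair(tree, 1.5, 1, 1, 50, seed=2)

    def test_reproducible(self):
        tree = sd.simulate_tree(5, seed=1)
        a1, _ = sd.simulate_family_pair(tree, 0.7, 2, 2, 80, seed=9)
        a2, _ = sd.simulate_family_pair(tree, 0.7, 2, 2, 80, seed=9)
        assert a1["A1"].rows == a2["A1"].rows


class TestSynthGenome:
    def test_planted_groups_recovered(self):
        loci, planted = sd.synth_genome(19, (2, 2, 2, 2), seed=5)
        found = detect_tandem(loci, "Wnt")
        assert sorted(tuple(g.members) for g in found) == sorted(planted)
        assert sum(len(g) for g in planted) == 8

    def test_no_groups_means_no_tandem(self):
        loci, planted = sd.synth_genome(10, (), seed=6)
        assert planted == []
        assert detect_tandem(loci, "Wnt") == []

    def test_oversized_groups_rejected(self):
        with pytest.raises(ValueError):
            sd.synth_genome(3, (2, 2), seed=0)
        with pytest.raises(ValueError):
            sd.synth_genome(5, (1,), seed=0)

    def test_reproducible(self):
        a, _ = sd.synth_genome(12, (2, 3), seed=7)
        b, _ = sd.synth_genome(12, (2, 3), seed=7)
        assert a == b


class TestSynthOrthologs:
    def test_planted_proportions_exact(self):
        counts = {"+++-": 10, "++--": 7, "+---": 1, "----": 1}
        presence = sd.synth_orthologs(counts, seed=3)
        summary = stratum_proportions(classify_presence(presence).values())
        assert summary.counts == {"++++": 0, "+++-": 10, "++--": 7,
                                  "+---": 1, "----": 1}

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            sd.synth_orthologs({"+*+-": 1}, seed=0)


class TestSynthExpression:
    def test_planted_shift_present(self):
        mat, truth = sd.synth_expression(
            n_genes=6, n_up=2, n_down=2, effect=3.0, noise_sd=0.01,
            n_per_group=4, seed=8,
        )
        calls = {c.gene_id: c.label for c in
                 classify_de(mat, "case", "control", mode="welch")}
        assert calls == truth

    def test_reproducible(self):
        m1, _ = sd.synth_expression(seed=4)
        m2, _ = sd.synth_expression(seed=4)
        assert m1.values.equals(m2.values)

    def test_too_many_planted_rejected(self):
        with pytest.raises(ValueError):
            sd.synth_expression(n_genes=4, n_up=3, n_down=3)


class TestSubstreams:
    def test_named_substreams_independent(self):
        a = sd.substream(11, "tree").integers(0, 1_000_000, 5)
        b = sd.substream(11, "genome").integers(0, 1_000_000, 5)
        a2 = sd.substream(11, "tree").integers(0, 1_000_000, 5)
        assert list(a) == list(a2)
        assert list(a) != list(b)
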