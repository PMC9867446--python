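import itertools

import numpy as np
import pytest

from clckit.phylo import (
    AA_ORDER,
    DistanceMatrix,
    PhyloError,
    PhyloTree,
    assign_subgroup,
    bootstrap_support,
    build_nj_tree,
    encode_sequence,
    load_jtt,
    ml_pairwise_distance,
    nni_neighbors,
    nni_search,
    optimize_branch_lengths,
    tree_log_likelihood,
)
from clckit.synthdata import simulate_evolution

from oracles import four_leaf_likelihood


class TestJttModel:
    def test_rate_matrix_rows_sum_to_zero(self, jtt):
        assert np.allclose(jtt.rate_matrix.sum(axis=1), 0.0, atol=1e-12)

    def test_detailed_balance(self, jtt):
        flux = jtt.pi[:, np.newaxis] * jtt.rate_matrix
        assert np.allclose(flux, flux.T, atol=1e-14)

    def test_unit_substitution_rate(self, jtt):
        assert -np.dot(jtt.pi, np.diag(jtt.rate_matrix)) == pytest.approx(1.0)

    def test_p0_is_identity(self, jtt):
        assert np.allclose(jtt.transition_matrix(0.0), np.eye(20), atol=1e-12)

    @pytest.mark.parametrize("t", [0.01, 0.1, 1.0, 10.0])
    def test_rows_sum_to_one(self, jtt, t):
        assert np.allclose(jtt.transition_matrix(t).sum(axis=1), 1.0, atol=1e-10)

    def test_chapman_kolmogorov(self, jtt):
        for t, s in [(0.1, 0.2), (0.5, 1.5), (0.01, 0.04)]:
            lhs = jtt.transition_matrix(t) @ jtt.transition_matrix(s)
            assert np.allclose(lhs, jtt.transition_matrix(t + s), atol=1e-8)

    def test_stationarity(self, jtt):
        assert np.allclose(jtt.pi @ jtt.transition_matrix(2.0), jtt.pi, atol=1e-12)

    def test_negative_time_rejected(self, jtt):
        with pytest.raises(PhyloError, match="nonnegative"):
            jtt.transition_matrix(-0.1)


class TestMlDistance:
    def test_identical_sequences_distance_zero(self, jtt):
        assert ml_pairwise_distance("MKWVTFISLL", "MKWVTFISLL", jtt) == 0.0

    def test_symmetry(self, jtt, rng):
        a = "".join(rng.choice(list(AA_ORDER), size=200))
        b = "".join(rng.choice(list(AA_ORDER), size=200))
        assert ml_pairwise_distance(a, b, jtt) == pytest.approx(
            ml_pairwise_distance(b, a, jtt), abs=1e-6
        )

    def test_gap_columns_dropped_pairwise(self, jtt):
        d_plain = ml_pairwise_distance("MKWVTFISLL", "MKWVTFISLL", jtt)
        d_gappy = ml_pairwise_distance("MKWVTFISLL", "MKWVTFIS--", jtt)
        assert d_plain == d_gappy == 0.0

    def test_no_shared_columns_rejected(self, jtt):
        with pytest.raises(PhyloError, match="no shared ungapped columns"):
            ml_pairwise_distance("MK--", "--MK", jtt)

    def test_recovers_simulated_branch_length(self, jtt):
        tree = PhyloTree.from_newick("(A:0.15,B:0.15);")
        leaves = simulate_evolution(10_000, tree, jtt, seed=42)
        estimate = ml_pairwise_distance(leaves["A"], leaves["B"], jtt)
        assert estimate == pytest.approx(0.3, abs=0.03)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        # d(A,B)=0.3, d(A,C)=0.5, d(B,C)=0.6 -> pendant edges 0.1, 0.2, 0.4
        d = DistanceMatrix(
            ["A", "B", "C"], np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        )
        tree = build_nj_tree(d)
        assert tree.path_length("A", "B") == pytest.approx(0.3)
        assert tree.path_length("A", "C") == pytest.approx(0.5)
        assert tree.path_length("B", "C") == pytest.approx(0.6)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(PhyloError, match=">= 3 taxa"):
            build_nj_tree(DistanceMatrix(["A", "B"], np.zeros((2, 2))))

    @staticmethod
    def eight_leaf_tree() -> PhyloTree:
        return PhyloTree.from_newick(
            "(((A:0.1,B:0.2):0.15,(C:0.12,D:0.08):0.2):0.1,"
            "((E:0.09,F:0.11):0.18,(G:0.14,H:0.1):0.12):0.1);"
        )

    def test_exact_recovery_from_additive_matrix(self):
        source = self.eight_leaf_tree()
        labels = source.leaf_labels()
        n = len(labels)
        m = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            m[i, j] = m[j, i] = source.path_length(labels[i], labels[j])
        recovered = build_nj_tree(DistanceMatrix(labels, m))
        assert recovered.splits() == source.splits()
        for a, b in itertools.combinations(labels, 2):
            assert recovered.path_length(a, b) == pytest.approx(
                source.path_length(a, b), abs=1e-9
            )

    def test_taxon_order_invariance(self):
        source = self.eight_leaf_tree()
        labels = source.leaf_labels()
        n = len(labels)
        m = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            m[i, j] = m[j, i] = source.path_length(labels[i], labels[j])
        perm = [3, 0, 7, 1, 5, 2, 6, 4]
        shuffled = DistanceMatrix(
            [labels[i] for i in perm], m[np.ix_(perm, perm)]
        )
        assert build_nj_tree(shuffled).splits() == source.splits()


class TestLikelihood:
    def test_two_taxa_single_site_closed_form(self, jtt):
        tree = PhyloTree.from_newick("(A:0.1,B:0.2);")
        x, y = AA_ORDER.index("M"), AA_ORDER.index("K")
        ll = tree_log_likelihood(tree, {"A": "M", "B": "K"}, jtt)
        expected = np.log(jtt.pi[x] * jtt.transition_matrix(0.3)[x, y])
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_root_placement_invariance(self, jtt):
        aln = {"A": "MKWV", "B": "MKYV", "C": "MRWV", "D": "LKWV"}
        t1 = PhyloTree.from_newick("((A:0.1,B:0.2):0.05,(C:0.15,D:0.1):0.07);")
        t2 = PhyloTree.from_newick("(A:0.02,((C:0.15,D:0.1):0.12,B:0.2):0.08);")
        # same unrooted tree written with different rootings
        assert tree_log_likelihood(t1, aln, jtt) == pytest.approx(
            tree_log_likelihood(t2, aln, jtt), abs=1e-8
        )

    def test_pruning_equals_exhaustive_enumeration(self, jtt):
        lengths = {"A": 0.1, "B": 0.25, "C": 0.07, "D": 0.3, "I": 0.12}
        tree = PhyloTree.from_newick(
            f"((A:{lengths['A']},B:{lengths['B']}):{lengths['I']},"
            f"C:{lengths['C']},D:{lengths['D']});"
        )
        aln = {"A": "MK", "B": "MR", "C": "LK", "D": "MW"}
        leaf_states = {k: [AA_ORDER.index(c) for c in v] for k, v in aln.items()}
        # the unrooted quartet splits the internal edge at the C/D junction
        oracle = four_leaf_likelihood(
            leaf_states,
            {"A": 0.1, "B": 0.25, "C": 0.07, "D": 0.3, "I": 0.12},
            jtt.pi,
            jtt.transition_matrix,
        )
        assert tree_log_likelihood(tree, aln, jtt) == pytest.approx(oracle, abs=1e-9)

    def test_gap_treated_as_missing_data(self, jtt):
        tree = PhyloTree.from_newick("(A:0.1,B:0.2);")
        ll_gap = tree_log_likelihood(tree, {"A": "M-", "B": "KX"}, jtt)
        ll_one = tree_log_likelihood(tree, {"A": "M", "B": "K"}, jtt)
        assert ll_gap == pytest.approx(ll_one, abs=1e-10)

    def test_missing_leaf_rejected(self, jtt):
        tree = PhyloTree.from_newick("(A:0.1,B:0.2);")
        with pytest.raises(PhyloError, match="missing from alignment"):
            tree_log_likelihood(tree, {"A": "M"}, jtt)


class TestNniSearch:
    @staticmethod
    def simulated_quartet(jtt, seed=7):
        truth = PhyloTree.from_newick("((A:0.1,B:0.1):0.3,(C:0.1,D:0.1):0.3);")
        aln = simulate_evolution(400, truth, jtt, seed=seed)
        return truth, aln

    def test_true_topology_is_a_local_optimum(self, jtt):
        truth, aln = self.simulated_quartet(jtt)
        result = nni_search(truth.copy(), aln, jtt, max_rounds=3)
        assert result.splits() == truth.splits()

    def test_recovers_truth_from_one_nni_away(self, jtt):
        truth, aln = self.simulated_quartet(jtt)
        u, v = truth.internal_edges()[0]
        wrong = nni_neighbors(truth, u, v)[0]
        assert wrong.splits() != truth.splits()
        result = nni_search(wrong, aln, jtt, max_rounds=3)
        assert result.splits() == truth.splits()

    def test_log_likelihood_non_decreasing(self, jtt):
        truth, aln = self.simulated_quartet(jtt)
        u, v = truth.internal_edges()[0]
        start = nni_neighbors(truth, u, v)[0]
        ll_start = optimize_branch_lengths(start.copy(), aln, jtt)
        result = nni_search(start, aln, jtt, max_rounds=3)
        ll_end = tree_log_likelihood(result, aln, jtt)
        assert ll_end >= ll_start - 1e-6


class TestBootstrap:
    @staticmethod
    def two_clade_alignment(jtt, nsites=300, seed=11):
        tree = PhyloTree.from_newick(
            "(((A:0.05,B:0.05):0.05,(C:0.05,D:0.05):0.05):0.5,"
            "((E:0.05,F:0.05):0.05,(G:0.05,H:0.05):0.05):0.5);"
        )
        return tree, simulate_evolution(nsites, tree, jtt, seed=seed)

    def test_supports_within_range_and_reproducible(self, jtt):
        _, aln = self.two_clade_alignment(jtt, nsites=120)
        t1 = bootstrap_support(aln, jtt, replicates=20, seed=3)
        t2 = bootstrap_support(aln, jtt, replicates=20, seed=3)
        assert t1.support == t2.support
        assert all(0.0 <= s <= 100.0 for s in t1.support.values())

    def test_deep_split_strongly_supported(self, jtt):
        _, aln = self.two_clade_alignment(jtt)
        tree = bootstrap_support(aln, jtt, replicates=100, seed=5)
        deep = frozenset("EFGH")
        assert deep in tree.support
        assert tree.support[deep] >= 95.0

    def test_single_replicate_gives_binary_supports(self, jtt):
        _, aln = self.two_clade_alignment(jtt, nsites=100)
        tree = bootstrap_support(aln, jtt, replicates=1, seed=9)
        assert set(tree.support.values()) <= {0.0, 100.0}

    def test_zero_variation_alignment_documented_behaviour(self, jtt):
        aln = {lab: "MKWVTFISLL" for lab in "ABCD"}
        tree = bootstrap_support(aln, jtt, replicates=5, seed=1)
        assert all(0.0 <= s <= 100.0 for s in tree.support.values())

    def test_zero_replicates_rejected(self, jtt):
        with pytest.raises(PhyloError, match="at least one"):
            bootstrap_support({"A": "M", "B": "M"}, jtt, replicates=0, seed=1)


class TestSubgroupAssignment:
    @staticmethod
    def family_tree() -> PhyloTree:
        return PhyloTree.from_newick(
            "(((AtCLCa:0.1,Qa:0.1):0.1,(AtCLCd:0.1,Qd:0.1):0.1):0.4,"
            "((AtCLCe:0.1,AtCLCf:0.1):0.1,Qf:0.1):0.4);"
        )

    def test_assignment_follows_anchor_clades(self):
        call = assign_subgroup(
            self.family_tree(), {"AtCLCa", "AtCLCd"}, {"AtCLCe", "AtCLCf"}
        )
        assert call["Qa"] == "I"
        assert call["Qd"] == "I"
        assert call["Qf"] == "II"
        assert call["AtCLCe"] == "II"

    def test_empty_anchor_set_rejected(self):
        with pytest.raises(PhyloError, match="non-empty"):
            assign_subgroup(self.family_tree(), {"AtCLCa"}, set())

    def test_missing_anchor_rejected(self):
        with pytest.raises(PhyloError, match="absent from tree"):
            assign_subgroup(self.family_tree(), {"AtCLCa"}, {"NOPE"})

    def test_interleaved_anchors_unassignable(self):
        tree = PhyloTree.from_newick(
            "((A1:0.1,B1:0.1):0.1,(A2:0.1,B2:0.1):0.1,(Q:0.1):0.1);"
        )
        call = assign_subgroup(tree, {"A1", "A2"}, {"B1", "B2"})
        assert call["Q"] == "unassignable"
        assert call["A1"] == "I"


class TestNewick:
    def test_round_trip_preserves_splits_and_lengths(self):
        tree = TestNeighborJoining.eight_leaf_tree()
        back = PhyloTree.from_newick(tree.to_newick())
        assert back.splits() == tree.splits()
        for a, b in itertools.combinations(tree.leaf_labels(), 2):
            assert back.path_length(a, b) == pytest.approx(tree.path_length(a, b))

    def test_supports_rendered_as_internal_labels(self, jtt):
        _, aln = TestBootstrap.two_clade_alignment(jtt, nsites=80)
        tree = bootstrap_support(aln, jtt, replicates=10, seed=2)
        text = tree.to_newick(include_support=True)
        import dendropy

        parsed = dendropy.Tree.get(data=text, schema="newick")
        assert {leaf.taxon.label for leaf in parsed.leaf_node_iter()} == set("ABCDEFGH")
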