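"""Heuristic distance machinery: preprocessing, Contract-Tree, both strategies."""
import pytest

from lrfdist import (
    Label, OpKind, TreeError, bipartition_set, classify_edges,
    contract_nonmixed_bad_edges, contract_tree, exact_distance,
    labeled_rf_estimate, methodology2, min_flips, parse_newick,
    random_labeled_tree, replay, rf_distance, star_path_cost,
    unroot_with_dummy, naive_upper_bound, canonical_key,
)
from conftest import (SPE, DUP, assert_isomorphic, proper_two_coloring,
                       star_tree, unrooted_quartet)


def assert_valid_witness(report, t1, t2):
    """The report's script must replay t1 into a tree isomorphic to t2."""
    assert report.total == report.script.total == \
        report.n_flips + report.n_contractions + report.n_extensions
    assert_isomorphic(replay(report.script, t1), t2)


class TestPreprocessing:
    def test_uniform_tree_contracts_all_bad_edges(self, worked_example):
        reduced, ops = contract_nonmixed_bad_edges(worked_example.T_prime, worked_example.T)
        assert len(ops) == 17
        assert len(reduced.internal_nodes()) == 2
        assert len(reduced.internal_edges()) == 1
        # the surviving internal edge is the shared (good) split
        assert bipartition_set(reduced) <= bipartition_set(worked_example.T)

    def test_fully_mixed_tree_needs_no_preprocessing(self, worked_example):
        reduced, ops = contract_nonmixed_bad_edges(worked_example.T, worked_example.T_prime)
        assert ops == []
        assert len(reduced.internal_edges()) == 18

    @pytest.mark.parametrize("seed", range(6))
    def test_each_contraction_drops_exact_distance_by_one(self, seed):
        t1 = random_labeled_tree(6, 0.3, seed=seed)
        t2 = random_labeled_tree(6, 0.3, seed=seed + 4000)
        cls = classify_edges(t1, t2)
        nonmixed_bad = [e for e in cls.bad_edges(1) if not cls.tree1[e].mixed]
        if not nonmixed_bad:
            pytest.skip("instance has no non-mixed bad edge")
        from lrfdist import apply_contraction
        contracted = apply_contraction(t1, nonmixed_bad[0])
        assert exact_distance(contracted, t2) == exact_distance(t1, t2) - 1


class TestMinFlips:
    def test_star_needs_no_flip(self):
        assert min_flips(star_tree("ABCD")) == 0

    def test_mixed_quartet_needs_one(self):
        assert min_flips(unrooted_quartet(SPE, DUP)) == 1

    def test_hub_tree_needs_six_flips(self, worked_example):
        assert min_flips(worked_example.T) == 6

    def test_non_mixed_tree_is_rejected(self):
        with pytest.raises(TreeError, match="not mixed"):
            min_flips(unrooted_quartet(SPE, SPE))


class TestContractTree:
    def test_star_input_yields_empty_script(self):
        script, star = contract_tree(star_tree("ABCDE", DUP))
        assert script.total == 0
        assert star.label(star.internal_nodes()[0]) is DUP

    def test_hub_tree(self, worked_example):
        script, star = contract_tree(worked_example.T)
        assert (script.n_flips, script.n_contractions) == (6, 18)
        assert star.label(star.internal_nodes()[0]) is SPE

    def test_uniform_counterpart_is_flip_free(self, worked_example):
        script, star = contract_tree(worked_example.T_prime)
        assert (script.n_flips, script.n_contractions) == (0, 18)
        assert star.label(star.internal_nodes()[0]) is SPE

    @pytest.mark.parametrize("wanted", [SPE, DUP])
    def test_preferred_final_label_is_honoured_on_odd_diameter(self, wanted):
        # a mixed quartet has two midpoints, so both labels are achievable
        script, star = contract_tree(unrooted_quartet(SPE, DUP), wanted)
        assert star.label(star.internal_nodes()[0]) is wanted
        assert script.n_flips == 1

    def test_script_is_replayable(self, worked_example):
        script, star = contract_tree(worked_example.T)
        assert_isomorphic(replay(script, worked_example.T), star)


class TestMethodology2:
    def test_identical_trees_cost_nothing(self):
        t = random_labeled_tree(10, 0.3, seed=1)
        report = methodology2(t, t.copy())
        assert report.total == 0

    def test_worked_example_pair_breakdown(self, worked_example):
        report = methodology2(worked_example.T, worked_example.T_prime)
        assert report.total == 43
        assert (report.n_flips, report.n_contractions,
                report.n_extensions) == (9, 17, 17)
        assert_valid_witness(report, worked_example.T, worked_example.T_prime)

    def test_swapped_labels_cost_one_flip_each(self):
        t1 = unrooted_quartet(SPE, DUP)
        t2 = unrooted_quartet(DUP, SPE)
        report = methodology2(t1, t2)
        assert report.total == 2 == exact_distance(t1, t2)
        assert_valid_witness(report, t1, t2)

    def test_rooted_inputs_are_rejected(self):
        r = parse_newick("((A,B)Spe,(C,D)Dup)Spe;")
        with pytest.raises(TreeError):
            methodology2(r, r)


class TestStarPath:
    def test_worked_example_pair_beats_methodology2(self, worked_example):
        report = star_path_cost(worked_example.T, worked_example.T_prime)
        assert report.total == 42
        assert (report.n_flips, report.n_contractions,
                report.n_extensions) == (6, 18, 18)
        assert_valid_witness(report, worked_example.T, worked_example.T_prime)

    def test_identical_uniform_trees_cost_twice_the_internal_edges(self):
        t = random_labeled_tree(8, 0.0, seed=3)
        for v in t.internal_nodes():
            t.set_label(v, SPE)
        m = len(t.internal_edges())
        assert star_path_cost(t, t.copy()).total == 2 * m

    def test_two_stars_with_different_labels_cost_one_flip(self):
        report = star_path_cost(star_tree("ABC", SPE), star_tree("ABC", DUP))
        assert report.total == 1 == report.n_flips


class TestLabeledRfEstimate:
    def test_worked_example_pair_picks_the_star_path(self, worked_example):
        report = labeled_rf_estimate(worked_example.T, worked_example.T_prime)
        assert report.total == 42
        assert report.method_tag == "star_path"
        assert report.alternatives == {"methodology2": 43, "star_path": 42}
        assert_valid_witness(report, worked_example.T, worked_example.T_prime)

    def test_identical_trees(self):
        t = random_labeled_tree(9, 0.2, seed=5)
        assert labeled_rf_estimate(t, t.copy()).total == 0

    @pytest.mark.parametrize("seed", range(8))
    def test_uniformly_labeled_pairs_reduce_to_classical_rf(self, seed):
        t1 = random_labeled_tree(9, 0.3, seed=seed)
        t2 = random_labeled_tree(9, 0.3, seed=seed + 7000)
        for t in (t1, t2):
            for v in t.internal_nodes():
                t.set_label(v, SPE)
        assert labeled_rf_estimate(t1, t2).total == rf_distance(t1, t2)

    def test_rooted_pair_uses_shared_dummy(self):
        r1 = parse_newick("(((A,B)Spe,C)Dup,(D,E)Spe)Spe;")
        r2 = parse_newick("(((A,C)Dup,B)Spe,(D,E)Dup)Dup;")
        report = labeled_rf_estimate(r1, r2)
        assert_isomorphic(replay(report.script, unroot_with_dummy(r1)),
                          unroot_with_dummy(r2))


class TestBounds:
    def test_bound_on_the_tight_binary_instance(self):
        assert naive_upper_bound(8, 8, 9) == 25
        assert naive_upper_bound(0, 0, 5) == 5

    def test_negative_counts_are_rejected(self):
        with pytest.raises(ValueError):
            naive_upper_bound(-1, 0, 0)

    @pytest.mark.parametrize("seed", range(10))
    def test_monotone_bound_chain(self, seed):
        """oracle <= estimate <= methodology2 <= e + e' + n."""
        t1 = random_labeled_tree(6, 0.3, seed=seed)
        t2 = random_labeled_tree(6, 0.3, seed=seed + 11_000)
        exact = exact_distance(t1, t2)
        est = labeled_rf_estimate(t1, t2)
        m2 = methodology2(t1, t2)
        cls = classify_edges(t1, t2)
        bound = naive_upper_bound(
            len(cls.bad_edges(1)), len(cls.bad_edges(2)),
            max(len(t1.internal_nodes()), len(t2.internal_nodes())))
        assert exact <= est.total <= m2.total <= bound
        assert_valid_witness(est, t1, t2)
        assert_valid_witness(m2, t1, t2)

    @pytest.mark.parametrize("seed", range(8))
    def test_single_pair_overhead_is_at_most_one(self, seed):
        """On a single mixed bad-subtree pair the heuristic's cost exceeds
        the two optimal contractions by at most one (the joining flip)."""
        t1 = proper_two_coloring(random_labeled_tree(6, 0.0, seed=seed))
        t2 = proper_two_coloring(random_labeled_tree(6, 0.0, seed=seed + 313))
        if bipartition_set(t1) & bipartition_set(t2):
            pytest.skip("pair shares a split; not a single bad subtree")
        cont1 = contract_tree(t1)[0].total
        cont2 = contract_tree(t2)[0].total
        m2 = methodology2(t1, t2).total
        assert cont1 + cont2 <= m2 <= cont1 + cont2 + 1
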