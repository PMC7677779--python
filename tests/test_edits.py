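"""Edit operations, scripts, replay and the random-edit simulator."""
import random

import pytest
from hypothesis import given, settings, strategies as st

from lrfdist import (
    EditError, EditScript, OpKind, apply_contraction, apply_extension,
    apply_flip, canonical_key, contract_op, exact_distance, flip_op, mutate,
    random_edit, random_labeled_tree, replay,
)
from conftest import (SPE, DUP, assert_isomorphic, proper_two_coloring,
                       star_tree, unrooted_quartet)


class TestContraction:
    def test_equal_label_edge_yields_star(self):
        t = unrooted_quartet(SPE, SPE)
        out = apply_contraction(t, tuple(t.internal_nodes()))
        assert_isomorphic(out, star_tree("ABCD", SPE))

    def test_mixed_edge_requires_flip_first(self):
        t = unrooted_quartet(SPE, DUP)
        with pytest.raises(EditError, match="flip"):
            apply_contraction(t, tuple(t.internal_nodes()))

    def test_terminal_edge_is_rejected(self):
        t = unrooted_quartet(SPE, SPE)
        x = t.internal_nodes()[0]
        leaf = next(v for v in t.neighbors(x) if t.is_leaf(v))
        with pytest.raises(EditError, match="terminal"):
            apply_contraction(t, (x, leaf))


class TestExtension:
    def test_star_split_yields_quartet(self):
        t = star_tree("ABCD", SPE)
        center = t.internal_nodes()[0]
        moved = {t.node_of_name("A"), t.node_of_name("B")}
        out = apply_extension(t, center, moved)
        assert_isomorphic(out, unrooted_quartet(SPE, SPE))

    def test_singleton_subset_is_rejected(self):
        t = star_tree("ABCD")
        with pytest.raises(EditError, match="at least 2"):
            apply_extension(t, t.internal_nodes()[0], {t.node_of_name("A")})

    def test_subset_leaving_degree_two_node_is_rejected(self):
        t = star_tree("ABCD")
        moved = {t.node_of_name(n) for n in "ABC"}
        with pytest.raises(EditError, match="degree-2"):
            apply_extension(t, t.internal_nodes()[0], moved)


class TestFlip:
    def test_flip_changes_only_the_label(self):
        t = star_tree("ABC", SPE)
        center = t.internal_nodes()[0]
        out = apply_flip(t, center, DUP)
        assert out.label(center) is DUP
        assert out.edges() == t.edges()

    def test_flip_to_same_label_is_rejected(self):
        t = star_tree("ABC", SPE)
        with pytest.raises(EditError):
            apply_flip(t, t.internal_nodes()[0], SPE)

    def test_flip_of_leaf_is_rejected(self):
        t = star_tree("ABC", SPE)
        with pytest.raises(EditError):
            apply_flip(t, t.node_of_name("A"), DUP)


@given(st.integers(min_value=0, max_value=10_000))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_extension_and_contraction_are_inverses(seed):
    """Splitting a node and contracting the created edge is the identity."""
    rng = random.Random(seed)
    t = random_labeled_tree(7, multifurcation_rate=0.5, seed=seed)
    fat = [v for v in t.internal_nodes() if t.degree(v) >= 4]
    if not fat:
        return
    node = rng.choice(fat)
    moved = frozenset(rng.sample(t.neighbors(node), 2))
    extended = apply_extension(t, node, moved)
    new_node = next(v for v in extended.neighbors(node) if v not in t)
    assert_isomorphic(apply_contraction(extended, (node, new_node)), t)


def test_contraction_then_extension_restores_tree():
    t = unrooted_quartet(SPE, SPE)
    x, y = t.internal_nodes()
    moved = frozenset(set(t.neighbors(y)) - {x})
    contracted = apply_contraction(t, (x, y))
    assert_isomorphic(apply_extension(contracted, x, moved), t)


class TestReplay:
    def test_empty_script_is_identity(self):
        t = unrooted_quartet(SPE, DUP)
        assert_isomorphic(replay(EditScript(ops=()), t), t)

    def test_illegal_op_reports_its_index(self):
        t = unrooted_quartet(SPE, DUP)
        x, y = t.internal_nodes()
        script = EditScript(ops=(flip_op(x, t.label(x).flipped()),
                                 contract_op(x, y),
                                 contract_op(x, y)))
        with pytest.raises(EditError, match="index 2"):
            replay(script, t)

    def test_mixed_edge_contraction_fails_at_its_index(self):
        t = unrooted_quartet(SPE, DUP)
        x, y = t.internal_nodes()
        with pytest.raises(EditError, match="index 0"):
            replay(EditScript(ops=(contract_op(x, y),)), t)

    def test_script_text_round_trip(self):
        t = star_tree("ABCDE", SPE)
        _, script = mutate(t, 4, seed=7)
        parsed = EditScript.from_text(script.to_text())
        assert parsed == script
        assert_isomorphic(replay(parsed, t), mutate(t, 4, seed=7)[0])


class TestRandomEdit:
    def test_fixed_seed_gives_identical_op_sequences(self):
        t = random_labeled_tree(10, 0.3, seed=3)
        ops1 = [random_edit(t, random.Random(11))[0] for _ in range(5)]
        ops2 = [random_edit(t, random.Random(11))[0] for _ in range(5)]
        assert ops1 == ops2

    def test_flip_changes_exactly_one_label(self):
        t = star_tree("ABCD", SPE)
        rng = random.Random(0)
        for _ in range(20):
            op, out = random_edit(t, rng)
            if op.kind is OpKind.FLIP:
                assert out.label(op.node) is t.label(op.node).flipped()
                assert out.edges() == t.edges()
                break
        else:  # pragma: no cover
            pytest.fail("no flip drawn in 20 tries")

    def test_binary_fully_mixed_tree_always_flips(self):
        t = proper_two_coloring(random_labeled_tree(6, 0.0, seed=5))
        rng = random.Random(1)
        kinds = {random_edit(t, rng)[0].kind for _ in range(40)}
        assert kinds == {OpKind.FLIP}

    def test_leaf_set_is_preserved(self):
        t = random_labeled_tree(9, 0.4, seed=2)
        rng = random.Random(9)
        for _ in range(30):
            _, t = random_edit(t, rng)
        assert t.leaf_names == random_labeled_tree(9, 0.4, seed=2).leaf_names


class TestMutate:
    def test_zero_edits_is_identity_with_empty_script(self):
        t = random_labeled_tree(8, 0.2, seed=4)
        out, script = mutate(t, 0, seed=1)
        assert script.total == 0
        assert_isomorphic(out, t)

    def test_fixed_seed_is_deterministic(self):
        t = random_labeled_tree(12, 0.3, seed=6)
        out1, s1 = mutate(t, 5, seed=42)
        out2, s2 = mutate(t, 5, seed=42)
        assert s1 == s2
        assert canonical_key(out1) == canonical_key(out2)

    def test_script_replays_to_the_returned_tree(self):
        t = random_labeled_tree(10, 0.3, seed=8)
        out, script = mutate(t, 6, seed=13)
        assert script.total == 6
        assert_isomorphic(replay(script, t), out)

    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_exact_distance_never_exceeds_edit_count(self, k):
        t = random_labeled_tree(6, 0.3, seed=21)
        out, _ = mutate(t, k, seed=50 + k)
        assert exact_distance(t, out) <= k
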