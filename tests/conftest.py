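"""Shared fixtures and small tree builders for the test suite."""
from __future__ import annotations

import random

import pytest

from lrfdist import Label, LabeledTree, canonical_key, worked_example_pair

SPE, DUP = Label.SPE, Label.DUP


def unrooted_quartet(label1: Label, label2: Label, split: str = "AB|CD") -> LabeledTree:
    """Unrooted binary quartet with the given split and internal labels."""
    side1, side2 = split.split("|")
    t = LabeledTree()
    x = t.add_internal(label1)
    y = t.add_internal(label2, attach_to=x)
    for name in side1:
        t.add_leaf(name, attach_to=x)
    for name in side2:
        t.add_leaf(name, attach_to=y)
    return t


def star_tree(names, label: Label = SPE) -> LabeledTree:
    t = LabeledTree()
    center = t.add_internal(label)
    for name in names:
        t.add_leaf(name, attach_to=center)
    return t


def root_on_edge(tree: LabeledTree, edge=None, label: Label = SPE) -> LabeledTree:
    """Root an unrooted tree by subdividing an edge with a binary root."""
    out = tree.copy()
    u, v = edge if edge is not None else out.edges()[0]
    r = out.add_internal(label)
    out.remove_edge(u, v)
    out.add_edge(r, u)
    out.add_edge(r, v)
    out.root = r
    return out


def proper_two_coloring(tree: LabeledTree, start_label: Label = SPE) -> LabeledTree:
    """Label internal nodes alternately so that every internal edge is mixed."""
    out = tree.copy()
    internal = out.internal_nodes()
    start = internal[0]
    lab = {start: start_label}
    stack = [start]
    while stack:
        u = stack.pop()
        for v in out.neighbors(u):
            if not out.is_leaf(v) and v not in lab:
                lab[v] = lab[u].flipped()
                stack.append(v)
    for v, l in lab.items():
        out.set_label(v, l)
    return out


def assert_isomorphic(t1: LabeledTree, t2: LabeledTree) -> None:
    assert canonical_key(t1) == canonical_key(t2)


@pytest.fixture(scope="session")
def worked_example():
    return worked_example_pair()


@pytest.fixture
def rng():
    return random.Random(20240901)
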