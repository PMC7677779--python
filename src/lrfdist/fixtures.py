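"""Deterministic fixtures, random labeled trees and the evaluation runner.

``worked_example_pair`` reconstructs the worked instance where contracting a good edge
beats handling the bad subtrees separately: a hub tree with three
alternating-label chains versus a uniformly speciation-labeled caterpillar
pair sharing exactly one non-trivial bipartition.  The topology of the
second tree is one concrete instance fixed so that every quoted count of the
worked example holds (18 internal edges each, one shared split, 9
minority-label nodes, 6 Contract-Tree flips, totals 42 vs 43); the fixture
verifies all of these programmatically at construction time.

``random_labeled_tree`` is a synthetic stand-in for a real gene-family tree:
a uniform sequential-attachment binary topology, optional random
multifurcations, and independent equiprobable speciation/duplication labels.
"""
from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .treemodel import Label, LabeledTree, TreeError, _check_valid
from .comparison import bipartition_set, rf_distance
from .edits import _random_edit_inplace
from .heuristic import labeled_rf_estimate


@dataclass(frozen=True)
class WorkedExamplePair:
    """The hub-and-chains tree T and its uniformly labeled counterpart T'."""

    T: LabeledTree
    T_prime: LabeledTree


def worked_example_pair() -> WorkedExamplePair:
    """Build the worked-example pair on a shared 21-name leaf set.

    ``T``: speciation hub with three chains of six internal nodes each
    (duplication at odd positions), pendant leaves ``X1..X5`` on the first
    five chain nodes and ``X6a, X6b`` on the last, for ``X`` in ``P, Q, R``.
    ``T'``: all-speciation tree with the same leaves arranged on two chains
    off a hub, sharing exactly the "all P leaves" split with ``T``.
    """
    T = LabeledTree()
    hub = T.add_internal(Label.SPE)
    for fam in "PQR":
        prev = hub
        for i in range(1, 7):
            x = T.add_internal(Label.DUP if i % 2 else Label.SPE,
                               attach_to=prev)
            if i < 6:
                T.add_leaf(f"{fam}{i}", attach_to=x)
            else:
                T.add_leaf(f"{fam}6a", attach_to=x)
                T.add_leaf(f"{fam}6b", attach_to=x)
            prev = x

    Tp = LabeledTree()
    h = Tp.add_internal(Label.SPE)
    Tp.add_leaf("Q1", attach_to=h)
    prev = h
    for pendant in ("P2", "P3", "P4", "P5", "P6a"):
        m = Tp.add_internal(Label.SPE, attach_to=prev)
        Tp.add_leaf(pendant, attach_to=m)
        prev = m
    m6 = Tp.add_internal(Label.SPE, attach_to=prev)
    Tp.add_leaf("P6b", attach_to=m6)
    Tp.add_leaf("P1", attach_to=m6)
    prev = h
    for pendant in ("R1", "Q2", "R2", "Q3", "R3", "Q4", "R4",
                    "Q5", "R5", "Q6a", "R6a"):
        n = Tp.add_internal(Label.SPE, attach_to=prev)
        Tp.add_leaf(pendant, attach_to=n)
        prev = n
    n12 = Tp.add_internal(Label.SPE, attach_to=prev)
    Tp.add_leaf("Q6b", attach_to=n12)
    Tp.add_leaf("R6b", attach_to=n12)

    _check_valid(T)
    _check_valid(Tp)
    checks = {
        "shared leaf set": T.leaf_names == Tp.leaf_names and T.n_leaves == 21,
        "19 internal nodes each": (len(T.internal_nodes()) == 19
                                   and len(Tp.internal_nodes()) == 19),
        "18 internal edges each": (len(T.internal_edges()) == 18
                                   and len(Tp.internal_edges()) == 18),
        "T fully mixed": T.is_mixed,
        "exactly one shared split":
            len(bipartition_set(T) & bipartition_set(Tp)) == 1,
        "minority label count 9":
            min(sum(1 for v in T.internal_nodes()
                    if T.label(v) is lab) for lab in Label) == 9,
    }
    failed = [name for name, ok in checks.items() if not ok]
    if failed:  # pragma: no cover - construction is deterministic
        raise RuntimeError("fixture invariants violated: " + ", ".join(failed))
    return WorkedExamplePair(T=T, T_prime=Tp)


def random_labeled_tree(n_leaves: int, multifurcation_rate: float = 0.0,
                        seed=None) -> LabeledTree:
    """Random unrooted labeled tree on ``n_leaves`` named leaves.

    Topology by sequential (Markovian) leaf attachment to a uniform random
    edge; each internal edge of the binary tree is then independently
    contracted with probability ``multifurcation_rate``; finally every
    internal node receives an independent equiprobable label.  Deterministic
    under ``seed`` (an int or a ``random.Random``).
    """
    if n_leaves < 3:
        raise TreeError("a labeled unrooted tree needs at least 3 leaves")
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    width = len(str(n_leaves))
    name = lambda i: f"L{str(i).zfill(width)}"

    t = LabeledTree()
    center = t.add_internal()
    for i in (1, 2, 3):
        t.add_leaf(name(i), attach_to=center)
    for i in range(4, n_leaves + 1):
        u, v = rng.choice(t.edges())
        m = t.add_internal()
        t.remove_edge(u, v)
        t.add_edge(m, u)
        t.add_edge(m, v)
        t.add_leaf(name(i), attach_to=m)

    if multifurcation_rate > 0:
        merged: dict = {}

        def find(x: int) -> int:
            while x in merged:
                x = merged[x]
            return x

        for u, v in t.internal_edges():
            if rng.random() < multifurcation_rate:
                ru, rv = find(u), find(v)
                keep, removed = min(ru, rv), max(ru, rv)
                t._contract(keep, removed)
                merged[removed] = keep

    for v in t.internal_nodes():
        t.set_label(v, rng.choice((Label.SPE, Label.DUP)))
    return _check_valid(t)


def evaluation_run(base_tree: LabeledTree, k_max: int, replicates: int,
                   seed=None) -> pd.DataFrame:
    """Random-edit benchmark of the labeled estimate against classical RF.

    For each replicate, applies ``k_max`` successive random edits to a copy
    of ``base_tree``, recording after each edit the classical RF distance
    and the labeled-RF estimate back to the base tree.  Returns a tidy table
    with columns ``k, replicate, rf_classical, labeled_estimate,
    true_edits`` (including the trivial ``k=0`` rows); byte-identical for a
    fixed seed.
    """
    if k_max < 1 or replicates < 1:
        raise ValueError("k_max and replicates must be >= 1")
    if base_tree.is_rooted:
        raise TreeError("evaluation_run expects an unrooted base tree")
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    rows = []
    for rep in range(1, replicates + 1):
        t = base_tree.copy()
        rows.append((0, rep, 0, 0, 0))
        for k in range(1, k_max + 1):
            _random_edit_inplace(t, rng)
            rows.append((k, rep,
                         rf_distance(base_tree, t),
                         labeled_rf_estimate(base_tree, t).total,
                         k))
    return pd.DataFrame(rows, columns=["k", "replicate", "rf_classical",
                                       "labeled_estimate", "true_edits"])
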