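"""Bipartition/clade machinery, classical RF distance and bad-subtree pairing.

The classical Robinson-Foulds distance between two unrooted trees on the same
leaf set is the size of the symmetric difference of their non-trivial
bipartition sets (clade sets in the rooted case).  An internal edge is *good*
when its bipartition occurs in the other tree and *bad* otherwise; terminal
edges are always good.  The connected components of internal nodes spanned by
bad edges are the *maximal bad subtrees*; each one has a unique counterpart
in the other tree with the same boundary of good-edge bipartitions, and these
matched pairs are the units the labeled-RF heuristic operates on.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .treemodel import LabeledTree, TreeError


@dataclass(frozen=True)
class Bipartition:
    """Unordered split of the leaf-name universe induced by removing an edge.

    Canonical form: ``side_a`` is the side containing the lexicographically
    smallest leaf name of the universe.
    """

    side_a: frozenset
    side_b: frozenset

    @classmethod
    def of(cls, one_side, universe) -> "Bipartition":
        one_side = frozenset(one_side)
        other = frozenset(universe) - one_side
        if not one_side or not other:
            raise TreeError("a bipartition needs two non-empty sides")
        smallest = min(min(one_side), min(other))
        if smallest in one_side:
            return cls(one_side, other)
        return cls(other, one_side)

    @property
    def is_trivial(self) -> bool:
        return min(len(self.side_a), len(self.side_b)) < 2

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        a = ",".join(sorted(self.side_a))
        b = ",".join(sorted(self.side_b))
        return f"{{{a}}}|{{{b}}}"

    def sort_key(self) -> tuple:
        return (tuple(sorted(self.side_a)), tuple(sorted(self.side_b)))


def _leaves_beyond(tree: LabeledTree, start: int, banned: int) -> frozenset:
    """Leaf names reachable from ``start`` without crossing ``banned``."""
    seen = {start}
    stack = [start]
    names = []
    while stack:
        u = stack.pop()
        if tree.is_leaf(u):
            names.append(tree.name_of(u))
            continue
        for v in tree.neighbors(u):
            if v != banned and v not in seen:
                seen.add(v)
                stack.append(v)
    return frozenset(names)


def edge_bipartitions(tree: LabeledTree) -> dict:
    """Map every edge (sorted tuple) to its :class:`Bipartition`.

    Includes trivial bipartitions of terminal edges; filter with
    ``is_trivial`` when only internal edges matter.
    """
    if tree.is_rooted:
        raise TreeError("bipartitions are defined for unrooted trees")
    universe = tree.leaf_names
    out = {}
    for u, v in tree.edges():
        side = _leaves_beyond(tree, v, banned=u)
        out[(u, v)] = Bipartition.of(side, universe)
    return out


def bipartition_set(tree: LabeledTree) -> frozenset:
    """The set of non-trivial bipartitions (one per internal edge)."""
    return frozenset(b for b in edge_bipartitions(tree).values()
                     if not b.is_trivial)


def clade_set(tree: LabeledTree) -> frozenset:
    """The set of non-trivial clades of a rooted tree.

    A clade is the leaf-name set below an internal node; the root clade (the
    full universe) and singleton clades are trivial and excluded.
    """
    if not tree.is_rooted:
        raise TreeError("clades are defined for rooted trees")
    universe = tree.leaf_names

    clades = {}

    def walk(v: int, parent: Optional[int]) -> frozenset:
        if tree.is_leaf(v):
            return frozenset({tree.name_of(v)})
        below = frozenset().union(*(walk(u, v) for u in tree.neighbors(v)
                                    if u != parent))
        clades[v] = below
        return below

    walk(tree.root, None)
    return frozenset(c for c in clades.values()
                     if 1 < len(c) < len(universe))


def _require_comparable(t1: LabeledTree, t2: LabeledTree) -> None:
    if t1.leaf_names != t2.leaf_names:
        raise TreeError("trees are on different leaf sets")
    if t1.is_rooted != t2.is_rooted:
        raise TreeError("cannot compare a rooted tree with an unrooted one")


def rf_distance(t1: LabeledTree, t2: LabeledTree, ignore_labels: bool = True) -> int:
    """Classical Robinson-Foulds distance (labels are not compared).

    For unrooted trees: ``|B(T1) \\ B(T2)| + |B(T2) \\ B(T1)|``; for rooted
    trees the same symmetric difference over clade sets.
    """
    if not ignore_labels:
        raise ValueError("the classical RF distance ignores labels; "
                         "use lrfdist.heuristic.labeled_rf_estimate for a "
                         "label-aware distance")
    _require_comparable(t1, t2)
    if t1.is_rooted:
        a, b = clade_set(t1), clade_set(t2)
    else:
        a, b = bipartition_set(t1), bipartition_set(t2)
    return len(a ^ b)


@dataclass(frozen=True)
class EdgeInfo:
    """Classification of one edge: shared-bipartition status and mixedness."""

    good: bool
    mixed: bool


@dataclass(frozen=True)
class EdgeClassification:
    """Per-edge :class:`EdgeInfo` maps for both compared trees."""

    tree1: dict
    tree2: dict

    def bad_edges(self, which: int) -> list:
        table = self.tree1 if which == 1 else self.tree2
        return sorted(e for e, info in table.items() if not info.good)


def classify_edges(t1: LabeledTree, t2: LabeledTree) -> EdgeClassification:
    """Classify every edge of both trees as good/bad and mixed/non-mixed.

    An internal edge is good iff its bipartition occurs in the other tree;
    terminal edges are always good and never mixed.
    """
    _require_comparable(t1, t2)
    if t1.is_rooted:
        raise TreeError("edge classification is defined for unrooted trees")

    def table(t: LabeledTree, other_bips: frozenset) -> dict:
        out = {}
        for edge, bip in edge_bipartitions(t).items():
            good = bip.is_trivial or bip in other_bips
            out[edge] = EdgeInfo(good=good, mixed=t.is_mixed_edge(*edge))
        return out

    b1, b2 = bipartition_set(t1), bipartition_set(t2)
    return EdgeClassification(tree1=table(t1, b2), tree2=table(t2, b1))


@dataclass(frozen=True)
class BadSubtreePair:
    """A maximal bad subtree of T matched to its unique counterpart in T'.

    ``nodes_in_t1`` / ``nodes_in_t2`` are the internal-node sets of the two
    matched components; ``boundary`` is their shared set of terminal-edge
    bipartitions (good internal edges and terminal leaf edges).
    """

    nodes_in_t1: frozenset
    nodes_in_t2: frozenset
    boundary: frozenset

    def sort_key(self) -> tuple:
        return tuple(sorted(b.sort_key() for b in self.boundary))


def _bad_components(tree: LabeledTree, table: dict) -> list:
    """Connected components of internal nodes under bad edges, with boundary.

    Returns ``[(node_set, boundary_bipartition_set), ...]``; singleton
    components (internal nodes with only good incident edges) are included.
    """
    bad_adj: dict[int, set[int]] = {v: set() for v in tree.internal_nodes()}
    for (u, v), info in table.items():
        if not info.good:
            bad_adj[u].add(v)
            bad_adj[v].add(u)

    bips = edge_bipartitions(tree)
    components = []
    seen: set[int] = set()
    for start in tree.internal_nodes():
        if start in seen:
            continue
        comp = {start}
        stack = [start]
        while stack:
            u = stack.pop()
            for v in bad_adj[u]:
                if v not in comp:
                    comp.add(v)
                    stack.append(v)
        seen |= comp
        boundary = set()
        for u in comp:
            for v in tree.neighbors(u):
                if v in comp and v in bad_adj[u]:
                    continue  # in-component bad edge
                boundary.add(bips[tuple(sorted((u, v)))])
        components.append((frozenset(comp), frozenset(boundary)))
    return components


def decompose_bad_subtrees(t1: LabeledTree, t2: LabeledTree) -> list:
    """Match the maximal bad subtrees of the two trees into pairs.

    Components are matched by their boundary bipartition sets; the matching
    is a perfect matching covering every internal node of both trees.  No
    contraction is performed here; preprocessing lives in the heuristic.
    """
    cls = classify_edges(t1, t2)
    comps1 = _bad_components(t1, cls.tree1)
    comps2 = _bad_components(t2, cls.tree2)
    by_boundary = {boundary: nodes for nodes, boundary in comps2}
    if len(by_boundary) != len(comps2):
        raise TreeError("ambiguous bad-subtree boundaries in second tree")
    pairs = []
    for nodes1, boundary in comps1:
        try:
            nodes2 = by_boundary.pop(boundary)
        except KeyError:
            raise TreeError(
                "no matching bad subtree in second tree for boundary "
                f"{sorted(b.sort_key() for b in boundary)}") from None
        pairs.append(BadSubtreePair(nodes_in_t1=nodes1, nodes_in_t2=nodes2,
                                    boundary=boundary))
    if by_boundary:
        raise TreeError("unmatched bad subtrees remain in second tree")
    return sorted(pairs, key=BadSubtreePair.sort_key)
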