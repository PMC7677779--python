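"""Labeled Robinson-Foulds distance estimation.

The estimator upper-bounds the labeled edit distance (flips, contractions,
extensions; all unit cost) between two labeled trees on the same leaf set by
producing an explicit edit script.  Two strategies are offered:

* **Methodology 2** — contract every non-mixed bad edge first (each such
  contraction provably reduces the true distance by exactly 1), split the
  trees into matched pairs of maximal bad subtrees, optimally contract both
  sides of each pair to a star with the Contract-Tree procedure while
  coordinating the two star labels, and add one flip per pair whose star
  labels are forced to differ.  This is a 2-approximation of the true
  distance.
* **Star path** — contract each whole tree (good edges included) to a single
  star and join the two paths, adding a flip if the star labels differ.  On
  some instances (notably trees whose bad subtrees can be "handled
  together") this beats Methodology 2.

Contract-Tree reduces a tree to a star with the minimum number of flips:
after contracting all non-mixed internal edges for free, the remaining tree
is mixed (every internal edge joins differently-labeled nodes) and exactly
``ceil(diam/2) - 1`` flips are needed.  The procedure starts at a *midpoint*
(a node of minimum leaf-eccentricity) and alternates one flip with the
contraction of all internal edges incident to it.  The final star label is
the midpoint's label flipped ``ecc - 1`` times, so enumerating midpoints
yields the set of achievable star labels.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

from .treemodel import (Label, LabeledTree, TreeError, geometry)
from .comparison import (bipartition_set, edge_bipartitions,
                         decompose_bad_subtrees, _require_comparable)
from .edits import (EditOp, EditScript, OpKind, apply_inplace,
                    contract_op, extend_op, flip_op)


@dataclass(frozen=True)
class DistanceReport:
    """An estimated labeled-RF distance with its witnessing edit script.

    ``replay(script, t1)`` is isomorphic (topology and labels) to ``t2``;
    ``total`` is always an upper bound on the true edit distance.
    ``alternatives`` records the totals of every strategy evaluated.
    """

    total: int
    n_flips: int
    n_contractions: int
    n_extensions: int
    script: EditScript
    method_tag: str
    alternatives: Optional[dict] = None


def _report(ops: list, tag: str) -> DistanceReport:
    script = EditScript(ops=tuple(ops))
    return DistanceReport(
        total=script.total, n_flips=script.n_flips,
        n_contractions=script.n_contractions, n_extensions=script.n_extensions,
        script=script, method_tag=tag)


def naive_upper_bound(e: int, e_prime: int, n: int) -> int:
    """Upper bound ``e + e' + n`` on the labeled edit distance.

    ``e`` and ``e'`` are the internal bad-edge counts of the two trees and
    ``n`` their internal-node count: contracting and re-extending every bad
    edge costs ``e + e'``, and at most the minority label group of each tree
    (so at most ``n`` nodes in total) ever needs flipping.
    """
    if e < 0 or e_prime < 0 or n < 0:
        raise ValueError("bad-edge and node counts must be non-negative")
    return e + e_prime + n


def _require_unrooted_pair(t1: LabeledTree, t2: LabeledTree) -> None:
    _require_comparable(t1, t2)
    if t1.is_rooted:
        raise TreeError("rooted inputs: convert with unroot_with_dummy first")


# ---------------------------------------------------------------------------
# Preprocessing: contract non-mixed bad edges
# ---------------------------------------------------------------------------

def _nonmixed_bad_inplace(w: LabeledTree, other_bips: frozenset) -> list:
    """Contract non-mixed bad edges of ``w`` until none remains.

    Contracting a bad edge never changes any other edge's bipartition, and
    the opposite tree only ever loses *its* bad bipartitions, so the
    good/bad status of surviving edges is stable; edges are still re-scanned
    after every contraction because merges create new incident non-mixed
    edges.  Returns forward records for later inversion.
    """
    records = []
    while True:
        bips = edge_bipartitions(w)
        cand = None
        for e in w.internal_edges():
            if bips[e] not in other_bips and w.label(e[0]) is w.label(e[1]):
                cand = e
                break
        if cand is None:
            return records
        keep, removed = cand
        moved = frozenset(w._adj[removed] - {keep})
        records.append(("cont", keep, removed, moved))
        w._contract(keep, removed)


def contract_nonmixed_bad_edges(t: LabeledTree, other: LabeledTree):
    """Exhaustively contract bad internal edges of ``t`` with equal labels.

    Returns ``(reduced_tree, contraction_ops)``.  After applying this to
    both trees of a pair, every remaining maximal bad subtree is mixed.
    """
    _require_unrooted_pair(t, other)
    w = t.copy()
    records = _nonmixed_bad_inplace(w, bipartition_set(other))
    ops = [contract_op(keep, removed) for _, keep, removed, _ in records]
    return w, ops


# ---------------------------------------------------------------------------
# Contract-Tree: optimal contraction to a star
# ---------------------------------------------------------------------------

def min_flips(t: LabeledTree) -> int:
    """Minimum flips to contract a mixed tree to a star: ``ceil(diam/2) - 1``."""
    if t.is_rooted:
        raise TreeError("min_flips is defined for unrooted trees")
    for u, v in t.internal_edges():
        if t.label(u) is t.label(v):
            raise TreeError(
                f"internal edge ({u}, {v}) is not mixed; contract non-mixed "
                "edges before computing the flip count")
    return math.ceil(geometry(t).diameter / 2) - 1


@dataclass(frozen=True)
class _ComponentPlan:
    """Star-contraction plan for one (sub)tree component.

    ``achievable`` maps each reachable final star label to the smallest
    midpoint node realising it; ``flips`` is the flip count any midpoint
    needs (``ceil(diam/2) - 1`` of the standalone component).
    """

    achievable: dict
    default_center: int
    flips: int

    def center_for(self, label: Optional[Label]) -> int:
        if label is not None and label in self.achievable:
            return self.achievable[label]
        return self.default_center


def _component_plan(tree: LabeledTree, comp: frozenset) -> _ComponentPlan:
    """Plan the contraction of the subtree spanned by ``comp``.

    The component is lifted to a standalone tree in which every boundary
    edge (terminal edge of the tree, or edge to a node outside ``comp``)
    becomes a terminal edge to a pseudo-leaf, exactly as a maximal bad
    subtree is measured: its diameter and eccentricities count those
    boundary edges.
    """
    comp = frozenset(comp)
    standalone = LabeledTree()
    fwd = {}
    back = {}
    for v in sorted(comp):
        nv = standalone.add_internal(tree.label(v))
        fwd[v] = nv
        back[nv] = v
    pseudo = 0
    for v in sorted(comp):
        for u in tree.neighbors(v):
            if u in comp:
                if u > v:
                    standalone.add_edge(fwd[v], fwd[u])
            else:
                pseudo += 1
                standalone.add_leaf(f"~{pseudo}", attach_to=fwd[v])
    geo = geometry(standalone)
    flips = math.ceil(geo.diameter / 2) - 1
    achievable: dict = {}
    centers = sorted(m for m in geo.midpoints if not standalone.is_leaf(m))
    for m in centers:
        final = standalone.label(m)
        if flips % 2:
            final = final.flipped()
        achievable.setdefault(final, back[m])
    return _ComponentPlan(achievable=achievable,
                          default_center=back[centers[0]], flips=flips)


def _contract_component(tree: LabeledTree, comp, center: int) -> list:
    """Contract the subtree spanned by ``comp`` onto ``center``, in place.

    Alternates flipping the center (when its in-component neighbors carry
    the other label) with contracting all in-component edges incident to it.
    Returns forward records (``("flip", node, old, new)`` /
    ``("cont", keep, removed, moved)``).
    """
    comp = set(comp)
    records = []
    while len(comp) > 1:
        ring = [u for u in tree.neighbors(center) if u in comp]
        if not ring:
            raise TreeError("component is not connected")  # pragma: no cover
        ring_labels = {tree.label(u) for u in ring}
        if len(ring_labels) != 1:
            raise TreeError("component is not mixed")  # pragma: no cover
        lab = ring_labels.pop()
        if tree.label(center) is not lab:
            records.append(("flip", center, tree.label(center), lab))
            tree._flip(center, lab)
        for u in sorted(ring):
            moved = frozenset(tree._adj[u] - {center})
            records.append(("cont", center, u, moved))
            tree._contract(center, u)
            comp.discard(u)
    return records


def _to_ops(records: list) -> list:
    ops = []
    for rec in records:
        if rec[0] == "flip":
            ops.append(flip_op(rec[1], rec[3]))
        else:
            ops.append(contract_op(rec[1], rec[2]))
    return ops


def _phase1_all_nonmixed(w: LabeledTree) -> list:
    """Contract every non-mixed internal edge (forward records)."""
    records = []
    while True:
        cand = None
        for e in w.internal_edges():
            if w.label(e[0]) is w.label(e[1]):
                cand = e
                break
        if cand is None:
            return records
        keep, removed = cand
        moved = frozenset(w._adj[removed] - {keep})
        records.append(("cont", keep, removed, moved))
        w._contract(keep, removed)


def contract_tree(t: LabeledTree,
                  preferred_final_label: Optional[Label] = None):
    """Optimally contract a tree to a star; returns ``(EditScript, star)``.

    Phase 1 contracts all non-mixed internal edges with zero flips; phase 2
    runs the midpoint flip-and-contract procedure on the resulting mixed
    tree.  The total is the internal-edge count plus ``ceil(diam/2) - 1``
    flips of the phase-2 tree.  When several final star labels are
    achievable (several midpoints), ``preferred_final_label`` is honoured.
    """
    if t.is_rooted:
        raise TreeError("contract_tree is defined for unrooted trees")
    w = t.copy()
    records = _phase1_all_nonmixed(w)
    if not w.is_star:
        plan = _component_plan(w, frozenset(w.internal_nodes()))
        center = plan.center_for(preferred_final_label)
        records += _contract_component(w, set(w.internal_nodes()), center)
    return EditScript(ops=tuple(_to_ops(records))), w


# ---------------------------------------------------------------------------
# Path assembly (inverting the second tree's contraction)
# ---------------------------------------------------------------------------

def _invert_records(w: LabeledTree, records: list, node_map: dict) -> list:
    """Replay ``records`` (recorded on the second tree) backwards on ``w``.

    Contractions become extensions, flips become flips back; ``node_map``
    carries the isomorphism from second-tree node ids to ``w`` node ids and
    is extended as extensions re-create nodes.  Ops are applied to ``w`` and
    returned.
    """
    ops = []
    for rec in reversed(records):
        if rec[0] == "cont":
            _, keep, removed, moved = rec
            op = extend_op(node_map[keep], (node_map[m] for m in moved))
            new_node = apply_inplace(w, op)
            node_map[removed] = new_node
        else:
            _, node, old, _new = rec
            op = flip_op(node_map[node], old)
            apply_inplace(w, op)
        ops.append(op)
    return ops


def _leaf_map(t_from: LabeledTree, t_to: LabeledTree) -> dict:
    return {t_from.node_of_name(name): t_to.node_of_name(name)
            for name in t_from.leaf_names}


def _coordinate(plan1: _ComponentPlan, plan2: _ComponentPlan):
    """Choose star labels for the two sides of a pair.

    Returns ``(center1, center2, residual_label)`` where ``residual_label``
    is the label the first side's star must still be flipped to (or None
    when a common label exists).
    """
    common = sorted(set(plan1.achievable) & set(plan2.achievable))
    if common:
        lab = common[0]
        return plan1.achievable[lab], plan2.achievable[lab], None
    lab1 = sorted(plan1.achievable)[0]
    lab2 = sorted(plan2.achievable)[0]
    return plan1.achievable[lab1], plan2.achievable[lab2], lab2


def methodology2(t1: LabeledTree, t2: LabeledTree) -> DistanceReport:
    """Bad-subtree-pair heuristic distance (factor-2 approximation).

    Steps: (i) contract all non-mixed bad edges of both trees; (ii) match
    the maximal bad subtrees into pairs; (iii) contract both sides of each
    pair to stars with coordinated final labels; (iv) one flip per pair
    whose star labels still differ.  Good edges are never contracted.  The
    second tree's operations are inverted into extensions, so the returned
    script is a valid path from ``t1`` to ``t2``.
    """
    _require_unrooted_pair(t1, t2)
    w, t2w = t1.copy(), t2.copy()

    ops = _to_ops(_nonmixed_bad_inplace(w, bipartition_set(t2)))
    records2 = _nonmixed_bad_inplace(t2w, bipartition_set(t1))

    node_map: dict = {}
    for pair in decompose_bad_subtrees(w, t2w):
        plan1 = _component_plan(w, pair.nodes_in_t1)
        plan2 = _component_plan(t2w, pair.nodes_in_t2)
        center1, center2, residual = _coordinate(plan1, plan2)
        pair_records = _contract_component(w, pair.nodes_in_t1, center1)
        ops += _to_ops(pair_records)
        if residual is not None:
            op = flip_op(center1, residual)
            apply_inplace(w, op)
            ops.append(op)
        records2 += _contract_component(t2w, pair.nodes_in_t2, center2)
        node_map[center2] = center1

    node_map.update(_leaf_map(t2w, w))
    ops += _invert_records(w, records2, node_map)
    return _report(ops, "methodology2")


def star_path_cost(t1: LabeledTree, t2: LabeledTree) -> DistanceReport:
    """Cost of the global path ``t1 -> star -> t2`` (good edges included).

    Both trees are fully contracted with Contract-Tree (coordinating the
    two star labels), and the second contraction is reversed into
    extensions; one flip joins the stars when their labels must differ.
    """
    _require_unrooted_pair(t1, t2)
    w, t2w = t1.copy(), t2.copy()

    records1 = _phase1_all_nonmixed(w)
    records2 = _phase1_all_nonmixed(t2w)
    plan1 = _component_plan(w, frozenset(w.internal_nodes()))
    plan2 = _component_plan(t2w, frozenset(t2w.internal_nodes()))
    center1, center2, residual = _coordinate(plan1, plan2)
    records1 += _contract_component(w, set(w.internal_nodes()), center1)
    records2 += _contract_component(t2w, set(t2w.internal_nodes()), center2)

    ops = _to_ops(records1)
    if residual is not None:
        op = flip_op(center1, residual)
        apply_inplace(w, op)
        ops.append(op)

    node_map = {center2: center1}
    node_map.update(_leaf_map(t2w, w))
    ops += _invert_records(w, records2, node_map)
    return _report(ops, "star_path")


def labeled_rf_estimate(t1: LabeledTree, t2: LabeledTree,
                        dummy_name: Optional[str] = None) -> DistanceReport:
    """Labeled-RF distance estimate: the cheaper of the two strategies.

    Rooted pairs are converted with :func:`unroot_with_dummy` (both trees
    must use the same dummy leaf); the witness script then acts on the
    dummy-unrooted trees.  The result is always an upper bound on the true
    edit distance, and both strategy totals are reported in
    ``alternatives``.
    """
    if t1.is_rooted != t2.is_rooted:
        raise TreeError("cannot compare a rooted tree with an unrooted one")
    if t1.is_rooted:
        from .treemodel import unroot_with_dummy, DEFAULT_DUMMY
        dummy = dummy_name or DEFAULT_DUMMY
        t1 = unroot_with_dummy(t1, dummy)
        t2 = unroot_with_dummy(t2, dummy)
    m2 = methodology2(t1, t2)
    sp = star_path_cost(t1, t2)
    best = m2 if m2.total <= sp.total else sp
    return replace(best, alternatives={"methodology2": m2.total,
                                       "star_path": sp.total})
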