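"""Exact labeled edit distance on small trees by search over the edit graph.

States are labeled unrooted trees on a fixed leaf-name set, identified up to
isomorphism by a canonical key; edges of the graph are the legal flips,
contractions and extensions (which are mutually inverse, so the graph is
undirected).  Breadth-first search gives the exact distance; the labeled
tree space on six leaves has only a few thousand states, so no efficiency
claims are needed — the oracle exists as ground truth for optimality and
approximation tests.
"""
from __future__ import annotations

from itertools import combinations
from typing import Optional

from .treemodel import LabeledTree, TreeError
from .comparison import classify_edges
from .edits import EditOp, apply_inplace, contract_op, extend_op, flip_op


def canonical_key(tree: LabeledTree) -> str:
    """Deterministic fingerprint, equal iff labeled-isomorphic.

    Computed as the lexicographic minimum, over every possible display
    root, of a recursive serialization whose leaves are the (fixed) leaf
    names and whose internal positions carry the node label with children
    sorted.  Leaf names anchor the recursion, so no leaf permutation is
    considered.
    """
    if tree.is_rooted:
        raise TreeError("canonical_key is defined for unrooted trees")
    memo: dict = {}
    adj = tree._adj

    def down(v: int, p: int) -> str:
        key = (v, p)
        r = memo.get(key)
        if r is None:
            if tree.is_leaf(v):
                r = tree.name_of(v)
            else:
                parts = sorted(down(u, v) for u in adj[v] if u != p)
                r = tree.label(v).value + "(" + ",".join(parts) + ")"
            memo[key] = r
        return r

    best = None
    for root in tree.nodes():
        if tree.is_leaf(root):
            head = tree.name_of(root)
        else:
            head = tree.label(root).value
        s = head + "(" + ",".join(sorted(down(u, root) for u in adj[root])) + ")"
        if best is None or s < best:
            best = s
    return best


def legal_ops(tree: LabeledTree, include_extensions: bool = True) -> list:
    """Every legal single edit op on ``tree`` (before isomorphism dedup)."""
    ops = []
    for v in tree.internal_nodes():
        ops.append(flip_op(v, tree.label(v).flipped()))
    for u, v in tree.internal_edges():
        if tree.label(u) is tree.label(v):
            ops.append(contract_op(u, v))
    if include_extensions:
        for v in tree.internal_nodes():
            deg = tree.degree(v)
            for size in range(2, deg - 1):
                for X in combinations(tree.neighbors(v), size):
                    ops.append(extend_op(v, X))
    return ops


def _neighbor_items(tree: LabeledTree, include_extensions: bool = True):
    """Yield ``(key, neighbor_tree)`` for each legal op (with duplicates)."""
    for op in legal_ops(tree, include_extensions):
        nb = tree.copy()
        apply_inplace(nb, op)
        yield canonical_key(nb), nb


def neighbors(tree: LabeledTree) -> list:
    """All trees one legal edit away, deduplicated by canonical key."""
    out: dict = {}
    for key, nb in _neighbor_items(tree):
        out.setdefault(key, nb)
    return [out[k] for k in sorted(out)]


def _default_bound(t1: LabeledTree, t2: LabeledTree) -> int:
    cls = classify_edges(t1, t2)
    e = len(cls.bad_edges(1))
    e_prime = len(cls.bad_edges(2))
    n = max(len(t1.internal_nodes()), len(t2.internal_nodes()))
    return e + e_prime + n


def exact_distance(t1: LabeledTree, t2: LabeledTree,
                   max_depth: Optional[int] = None,
                   bidirectional: bool = False) -> int:
    """Length of a shortest edit path between two labeled trees.

    Plain BFS from ``t1`` with early exit on ``t2``'s canonical key;
    ``bidirectional=True`` meets in the middle instead (same result, fewer
    states).  ``max_depth`` defaults to the always-sufficient upper bound
    ``e + e' + n`` (bad edges of each tree plus internal nodes); exceeding
    it raises.  Intended for trees with at most ~7 leaves.
    """
    if t1.leaf_names != t2.leaf_names:
        raise TreeError("trees are on different leaf sets")
    if t1.is_rooted or t2.is_rooted:
        raise TreeError("exact_distance is defined for unrooted trees")
    if max_depth is None:
        max_depth = _default_bound(t1, t2)
    k1, k2 = canonical_key(t1), canonical_key(t2)
    if k1 == k2:
        return 0

    if not bidirectional:
        dist = {k1: 0}
        frontier = {k1: t1}
        for depth in range(1, max_depth + 1):
            nxt: dict = {}
            for tree in frontier.values():
                for key, nb in _neighbor_items(tree):
                    if key == k2:
                        return depth
                    if key not in dist:
                        dist[key] = depth
                        nxt[key] = nb
            if not nxt:
                break
            frontier = nxt
        raise TreeError(f"no edit path of length <= {max_depth} found")

    # meet-in-the-middle; a first meeting may not be optimal, so expansion
    # continues until the two completed depths cover the best total found
    dist_a, dist_b = {k1: 0}, {k2: 0}
    front_a, front_b = {k1: t1}, {k2: t2}
    depth_a = depth_b = 0
    best: Optional[int] = None
    while front_a and front_b and depth_a + depth_b < max_depth:
        if best is not None and depth_a + depth_b >= best:
            break
        if len(front_a) <= len(front_b):
            front, dist, other = front_a, dist_a, dist_b
            depth_a += 1
            depth = depth_a
        else:
            front, dist, other = front_b, dist_b, dist_a
            depth_b += 1
            depth = depth_b
        nxt: dict = {}
        for tree in front.values():
            for key, nb in _neighbor_items(tree):
                if key not in dist:
                    dist[key] = depth
                    nxt[key] = nb
                    if key in other:
                        total = depth + other[key]
                        if best is None or total < best:
                            best = total
        if front is front_a:
            front_a = nxt
        else:
            front_b = nxt
    if best is not None and best <= max_depth:
        return best
    raise TreeError(f"no edit path of length <= {max_depth} found")
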