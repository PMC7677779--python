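"""Event-labeled phylogenetic trees: data model, Newick/NHX I/O and geometry.

A labeled tree is a rooted or unrooted multifurcating tree whose leaves carry
distinct names and whose internal nodes each carry one of exactly two event
labels, canonically ``Spe`` (speciation) and ``Dup`` (duplication).  Every
internal node of an unrooted tree must have degree >= 3; a rooted tree
distinguishes one internal node as the root, which may have degree 2.

Labels are read from Newick either as internal node name tokens
(``(A,B)Spe``) or as NHX duplication tags (``(A,B)[&&NHX:D=Y]``).
"""
from __future__ import annotations

import enum
import io
import math
from dataclasses import dataclass, field
from typing import Iterator, Optional, Union

import dendropy


class TreeError(ValueError):
    """Invalid tree structure or invalid operation on a tree."""


class NewickParseError(TreeError):
    """Malformed Newick input or undecodable node labels."""


class Label(enum.Enum):
    """One of the two internal-node event labels."""

    SPE = "Spe"
    DUP = "Dup"

    def flipped(self) -> "Label":
        """The other label; an involution (``flip(flip(x)) == x``)."""
        return Label.DUP if self is Label.SPE else Label.SPE

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    def __lt__(self, other: "Label") -> bool:
        # deterministic ordering (SPE < DUP) for tie-breaking
        return self is Label.SPE and other is Label.DUP


# ---------------------------------------------------------------------------
# Label codecs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NameCodec:
    """Encode labels as internal node name strings (case-insensitive match)."""

    spe_names: frozenset = frozenset({"spe", "speciation"})
    dup_names: frozenset = frozenset({"dup", "duplication"})

    def decode(self, name: Optional[str], comments: tuple) -> Optional[Label]:
        if name is None:
            return None
        low = name.strip().lower()
        if low in self.spe_names:
            return Label.SPE
        if low in self.dup_names:
            return Label.DUP
        return None

    def encode(self, label: Label) -> tuple:
        return (label.value, None)


@dataclass(frozen=True)
class NhxCodec:
    """Encode labels as NHX duplication tags: ``D=Y`` -> DUP, ``D=N`` -> SPE."""

    def decode(self, name: Optional[str], comments: tuple) -> Optional[Label]:
        for comment in comments:
            body = comment.strip()
            if not body.upper().startswith("&&NHX"):
                continue
            for item in body.split(":")[1:]:
                if "=" not in item:
                    continue
                key, _, value = item.partition("=")
                if key.strip().upper() == "D":
                    v = value.strip().upper()
                    if v == "Y":
                        return Label.DUP
                    if v == "N":
                        return Label.SPE
                    raise NewickParseError(f"unrecognised NHX D= value: {value!r}")
        return None

    def encode(self, label: Label) -> tuple:
        return (None, "&&NHX:D=%s" % ("Y" if label is Label.DUP else "N"))


Codec = Union[NameCodec, NhxCodec]

_CODECS = {"name": NameCodec(), "nhx": NhxCodec()}


def get_codec(codec: Union[str, Codec]) -> Codec:
    if isinstance(codec, str):
        try:
            return _CODECS[codec]
        except KeyError:
            raise NewickParseError(f"unknown label codec {codec!r}") from None
    return codec


# ---------------------------------------------------------------------------
# The tree container
# ---------------------------------------------------------------------------

class LabeledTree:
    """Mutable labeled tree over integer node identifiers.

    Node identifiers are arbitrary internal integers; tree equality is
    labeled-topology isomorphism (see :func:`lrfdist.oracle.canonical_key`),
    never identifier equality.  An instance is *rooted* when :attr:`root`
    is not ``None``.
    """

    __slots__ = ("_adj", "_labels", "_leaf_name", "_name_to_id", "root", "_next_id")

    def __init__(self) -> None:
        self._adj: dict[int, set[int]] = {}
        self._labels: dict[int, Label] = {}
        self._leaf_name: dict[int, str] = {}
        self._name_to_id: dict[str, int] = {}
        self.root: Optional[int] = None
        self._next_id: int = 0

    # -- construction -------------------------------------------------------

    def add_internal(self, label: Optional[Label] = None, attach_to: Optional[int] = None) -> int:
        """Create an internal node (optionally attached to an existing node)."""
        v = self._next_id
        self._next_id += 1
        self._adj[v] = set()
        if label is not None:
            self._labels[v] = label
        if attach_to is not None:
            self.add_edge(v, attach_to)
        return v

    def add_leaf(self, name: str, attach_to: Optional[int] = None) -> int:
        if name in self._name_to_id:
            raise TreeError(f"duplicate leaf name {name!r}")
        v = self._next_id
        self._next_id += 1
        self._adj[v] = set()
        self._leaf_name[v] = name
        self._name_to_id[name] = v
        if attach_to is not None:
            self.add_edge(v, attach_to)
        return v

    def add_edge(self, u: int, v: int) -> None:
        self._adj[u].add(v)
        self._adj[v].add(u)

    def remove_edge(self, u: int, v: int) -> None:
        self._adj[u].discard(v)
        self._adj[v].discard(u)

    def set_label(self, v: int, label: Label) -> None:
        if self.is_leaf(v):
            raise TreeError(f"cannot label leaf node {v}")
        self._labels[v] = label

    # -- inspection ---------------------------------------------------------

    @property
    def is_rooted(self) -> bool:
        return self.root is not None

    def nodes(self) -> list[int]:
        return sorted(self._adj)

    def __contains__(self, v: int) -> bool:
        return v in self._adj

    def __len__(self) -> int:
        return len(self._adj)

    def is_leaf(self, v: int) -> bool:
        return v in self._leaf_name

    def leaves(self) -> list[int]:
        return sorted(self._leaf_name)

    def internal_nodes(self) -> list[int]:
        return sorted(v for v in self._adj if v not in self._leaf_name)

    @property
    def n_leaves(self) -> int:
        return len(self._leaf_name)

    @property
    def leaf_names(self) -> frozenset:
        return frozenset(self._name_to_id)

    def name_of(self, v: int) -> str:
        return self._leaf_name[v]

    def node_of_name(self, name: str) -> int:
        return self._name_to_id[name]

    def degree(self, v: int) -> int:
        return len(self._adj[v])

    def neighbors(self, v: int) -> tuple:
        return tuple(sorted(self._adj[v]))

    def label(self, v: int) -> Label:
        try:
            return self._labels[v]
        except KeyError:
            raise TreeError(f"node {v} has no label") from None

    def has_label(self, v: int) -> bool:
        return v in self._labels

    def edges(self) -> list[tuple]:
        """All edges as sorted (u, v) tuples with u < v, in sorted order."""
        out = []
        for u in self._adj:
            for v in self._adj[u]:
                if u < v:
                    out.append((u, v))
        out.sort()
        return out

    def internal_edges(self) -> list[tuple]:
        return [e for e in self.edges()
                if e[0] not in self._leaf_name and e[1] not in self._leaf_name]

    def is_internal_edge(self, u: int, v: int) -> bool:
        return (u not in self._leaf_name and v not in self._leaf_name
                and v in self._adj.get(u, ()))

    def is_mixed_edge(self, u: int, v: int) -> bool:
        """True for an internal edge whose endpoint labels differ."""
        return self.is_internal_edge(u, v) and self._labels[u] is not self._labels[v]

    @property
    def is_star(self) -> bool:
        return len(self._adj) - len(self._leaf_name) == 1

    @property
    def is_mixed(self) -> bool:
        """True when every internal edge is mixed."""
        return all(self._labels[u] is not self._labels[v]
                   for u, v in self.internal_edges())

    def copy(self) -> "LabeledTree":
        t = LabeledTree.__new__(LabeledTree)
        t._adj = {v: set(nb) for v, nb in self._adj.items()}
        t._labels = dict(self._labels)
        t._leaf_name = dict(self._leaf_name)
        t._name_to_id = dict(self._name_to_id)
        t.root = self.root
        t._next_id = self._next_id
        return t

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "rooted" if self.is_rooted else "unrooted"
        return (f"<LabeledTree {kind}, {self.n_leaves} leaves, "
                f"{len(self._adj) - self.n_leaves} internal nodes>")

    # -- in-place edit primitives (validation lives in lrfdist.edits) -------

    def _contract(self, keep: int, remove: int) -> None:
        """Merge ``remove`` into ``keep`` along their shared edge."""
        for z in self._adj[remove]:
            if z == keep:
                continue
            self._adj[z].discard(remove)
            self._adj[z].add(keep)
            self._adj[keep].add(z)
        self._adj[keep].discard(remove)
        del self._adj[remove]
        self._labels.pop(remove, None)
        if self.root == remove:
            self.root = keep

    def _extend(self, node: int, moved: frozenset) -> int:
        """Split ``moved`` neighbors of ``node`` off onto a new same-label node."""
        y = self._next_id
        self._next_id += 1
        self._adj[y] = set()
        self._labels[y] = self._labels[node]
        for z in moved:
            self.remove_edge(node, z)
            self.add_edge(y, z)
        self.add_edge(node, y)
        return y

    def _flip(self, node: int, new_label: Label) -> None:
        self._labels[node] = new_label


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate(tree: LabeledTree) -> list[str]:
    """Return a list of invariant violations (empty when the tree is valid).

    Violations are reported as human-readable strings naming the offending
    node; they are data, not exceptions.
    """
    problems: list[str] = []
    nodes = tree.nodes()
    if not nodes:
        return ["tree has no nodes"]

    # connectivity + acyclicity
    seen = {nodes[0]}
    stack = [nodes[0]]
    n_edges = 0
    while stack:
        u = stack.pop()
        for v in tree.neighbors(u):
            n_edges += 1
            if v not in seen:
                seen.add(v)
                stack.append(v)
    if len(seen) != len(nodes):
        problems.append("tree is not connected")
    elif n_edges // 2 != len(nodes) - 1:
        problems.append("tree contains a cycle")

    for v in nodes:
        deg = tree.degree(v)
        if tree.is_leaf(v):
            if deg != 1:
                problems.append(f"leaf {v} ({tree.name_of(v)!r}) has degree {deg}")
            if tree.has_label(v):
                problems.append(f"leaf {v} carries a label")
        else:
            if not tree.has_label(v):
                problems.append(f"internal node {v} has no label")
            min_deg = 2 if v == tree.root else 3
            if deg < min_deg:
                problems.append(f"internal node {v} has degree {deg} < {min_deg}")
    if tree.root is not None and tree.is_leaf(tree.root):
        problems.append("root is a leaf")
    return problems


def _check_valid(tree: LabeledTree) -> LabeledTree:
    problems = validate(tree)
    if problems:
        raise TreeError("invalid tree: " + "; ".join(problems))
    return tree


# ---------------------------------------------------------------------------
# Newick / NHX I/O
# ---------------------------------------------------------------------------

def parse_newick(text: str, codec: Union[str, Codec] = "name",
                 suppress_unary: bool = False) -> LabeledTree:
    """Parse a Newick string into a validated :class:`LabeledTree`.

    The top-level node determines rootedness: degree 2 yields a rooted tree,
    degree >= 3 an unrooted one.  Branch lengths are parsed but discarded.
    Every internal node must carry a decodable label.  Internal nodes of
    degree 2 below the top level are rejected unless ``suppress_unary`` is
    set, in which case they are removed and their (redundant) label dropped;
    suppression is refused when it would discard a label that conflicts with
    both adjacent internal nodes.
    """
    codec = get_codec(codec)
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
            extract_comment_metadata=False,
        )
    except Exception as exc:  # dendropy raises a family of reader errors
        raise NewickParseError(f"Newick syntax error: {exc}") from exc

    tree = LabeledTree()
    seed = dtree.seed_node
    id_of: dict = {}

    for nd in dtree.preorder_node_iter():
        is_leaf = len(nd.child_nodes()) == 0
        if is_leaf:
            name = nd.taxon.label if nd.taxon is not None else nd.label
            if name is None:
                raise NewickParseError("leaf without a name")
            if name in tree._name_to_id:
                raise NewickParseError(f"duplicate leaf name {name!r}")
            v = tree.add_leaf(name)
        else:
            label = codec.decode(nd.label, tuple(nd.comments))
            if label is None:
                raise NewickParseError(
                    f"internal node {nd.label!r} has no decodable event label")
            v = tree.add_internal(label)
        id_of[nd] = v
        if nd.parent_node is not None:
            tree.add_edge(v, id_of[nd.parent_node])

    top = id_of[seed]
    top_degree = tree.degree(top)
    if top_degree < 2:
        raise NewickParseError("top-level node has degree < 2")
    tree.root = top if top_degree == 2 else None

    if suppress_unary:
        for v in tree.internal_nodes():
            if v == tree.root or tree.degree(v) != 2:
                continue
            a, b = tree.neighbors(v)
            internal_nbrs = [u for u in (a, b) if not tree.is_leaf(u)]
            if internal_nbrs and all(tree.label(u) is not tree.label(v)
                                     for u in internal_nbrs):
                raise NewickParseError(
                    f"cannot suppress degree-2 node {v}: its label conflicts "
                    "with every adjacent internal node")
            tree.remove_edge(v, a)
            tree.remove_edge(v, b)
            tree.add_edge(a, b)
            del tree._adj[v]
            tree._labels.pop(v, None)

    return _check_valid(tree)


def _min_leaf_below(tree: LabeledTree, v: int, parent: Optional[int],
                    cache: dict) -> str:
    key = (v, parent)
    if key in cache:
        return cache[key]
    if tree.is_leaf(v):
        out = tree.name_of(v)
    else:
        out = min(_min_leaf_below(tree, u, v, cache)
                  for u in tree.neighbors(v) if u != parent)
    cache[key] = out
    return out


def write_newick(tree: LabeledTree, codec: Union[str, Codec] = "name") -> str:
    """Serialize a tree to Newick with a canonical child order.

    Children are emitted in increasing order of the smallest leaf name in
    their subtree, so ``parse_newick(write_newick(t))`` is isomorphic to
    ``t`` and the output is reproducible.  Rooted trees are written from the
    root; unrooted trees from their smallest-identifier internal node.
    """
    codec = get_codec(codec)
    _check_valid(tree)
    display_root = tree.root if tree.is_rooted else tree.internal_nodes()[0]
    cache: dict = {}

    def render(v: int, parent: Optional[int]) -> str:
        if tree.is_leaf(v):
            return tree.name_of(v)
        children = sorted((u for u in tree.neighbors(v) if u != parent),
                          key=lambda u: _min_leaf_below(tree, u, v, cache))
        name, comment = codec.encode(tree.label(v))
        suffix = (name or "") + (f"[{comment}]" if comment else "")
        return "(" + ",".join(render(u, v) for u in children) + ")" + suffix

    return render(display_root, None) + ";"


# ---------------------------------------------------------------------------
# Rooted <-> unrooted conversion
# ---------------------------------------------------------------------------

DEFAULT_DUMMY = "__ROOT__"


def unroot_with_dummy(tree: LabeledTree, dummy_name: str = DEFAULT_DUMMY) -> LabeledTree:
    """Unroot a rooted tree by attaching a dummy leaf to the root.

    The former root gains one degree (so a binary root becomes a valid
    degree-3 internal node) and all labels are preserved.  Both trees of a
    comparison must use the same ``dummy_name``.
    """
    if not tree.is_rooted:
        raise TreeError("tree is already unrooted")
    if dummy_name in tree.leaf_names:
        raise TreeError(f"dummy name {dummy_name!r} collides with a leaf name")
    out = tree.copy()
    out.add_leaf(dummy_name, attach_to=out.root)
    out.root = None
    return _check_valid(out)


# ---------------------------------------------------------------------------
# Metric geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Geometry:
    """Leaf-to-leaf metric summary of an unrooted tree.

    ``diameter`` is the edge count of the longest leaf-to-leaf chain;
    ``eccentricity[v]`` is the maximum edge distance from ``v`` to any leaf;
    ``midpoints`` are the nodes of minimum eccentricity, which always equals
    ``ceil(diameter / 2)``.
    """

    diameter: int
    eccentricity: dict
    midpoints: frozenset


def geometry(tree: LabeledTree) -> Geometry:
    """Compute diameter, per-node leaf eccentricity and the midpoint set."""
    if tree.is_rooted:
        raise TreeError("geometry is defined for unrooted trees")
    if tree.n_leaves < 2:
        raise TreeError("geometry requires at least 2 leaves")
    ecc = {v: 0 for v in tree.nodes()}
    diameter = 0
    for leaf in tree.leaves():
        dist = {leaf: 0}
        frontier = [leaf]
        while frontier:
            nxt = []
            for u in frontier:
                for w in tree.neighbors(u):
                    if w not in dist:
                        dist[w] = dist[u] + 1
                        nxt.append(w)
            frontier = nxt
        for v, d in dist.items():
            if d > ecc[v]:
                ecc[v] = d
            if v in tree._leaf_name and d > diameter:
                diameter = d
    target = math.ceil(diameter / 2)
    midpoints = frozenset(v for v, d in ecc.items() if d == target)
    return Geometry(diameter=diameter, eccentricity=ecc, midpoints=midpoints)
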