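"""The three labeled edit operations, edit scripts and the random-edit simulator.

Unit-cost operations on labeled trees:

* **contraction** of an internal edge whose endpoints share a label (the
  merged node keeps that label);
* **extension** of an internal node ``x``: a proper subset ``X`` of its
  neighbors with ``2 <= |X| <= degree(x) - 2`` is moved onto a new node that
  copies ``x``'s label (the inverse of a contraction);
* **flip** of an internal node's label to the other label.

The upper bound ``|X| <= degree - 2`` is stricter than the bare definition
(``X`` a proper neighbor subset): moving ``degree - 1`` neighbors would leave
a degree-2 internal node, which is not a valid evolutionary tree, so the tree
class would not be closed under edits.

The random-edit simulator follows the published protocol: with probability
0.3 a uniform random internal node is flipped; the remaining mass is spread
uniformly over all contractible internal edges (equal-label endpoints) and
all expandable nodes (degree > 3).  When that pool is empty the simulator
falls back to a flip.
"""
from __future__ import annotations

import enum
import random
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .treemodel import Label, LabeledTree, TreeError


class EditError(TreeError):
    """An edit operation violating its preconditions."""


class OpKind(enum.Enum):
    FLIP = "FLIP"
    CONTRACT = "CONTRACT"
    EXTEND = "EXTEND"


@dataclass(frozen=True)
class EditOp:
    """One edit operation, referencing nodes of the tree it applies to.

    ``CONTRACT`` edges are ordered: the first node survives the merge.
    """

    kind: OpKind
    node: Optional[int] = None          # FLIP / EXTEND target
    new_label: Optional[Label] = None   # FLIP only
    edge: Optional[tuple] = None        # CONTRACT: (keep, remove)
    moved: Optional[frozenset] = None   # EXTEND: neighbor subset X

    def __str__(self) -> str:
        if self.kind is OpKind.FLIP:
            return f"FLIP {self.node} {self.new_label.value}"
        if self.kind is OpKind.CONTRACT:
            return f"CONTRACT {self.edge[0]} {self.edge[1]}"
        return f"EXTEND {self.node} " + ",".join(map(str, sorted(self.moved)))


def flip_op(node: int, new_label: Label) -> EditOp:
    return EditOp(OpKind.FLIP, node=node, new_label=new_label)


def contract_op(keep: int, remove: int) -> EditOp:
    return EditOp(OpKind.CONTRACT, edge=(keep, remove))


def extend_op(node: int, moved: Iterable[int]) -> EditOp:
    return EditOp(OpKind.EXTEND, node=node, moved=frozenset(moved))


@dataclass(frozen=True)
class EditScript:
    """An ordered sequence of edit operations with per-type counts."""

    ops: tuple

    def __len__(self) -> int:
        return len(self.ops)

    def __iter__(self):
        return iter(self.ops)

    def _count(self, kind: OpKind) -> int:
        return sum(1 for op in self.ops if op.kind is kind)

    @property
    def n_flips(self) -> int:
        return self._count(OpKind.FLIP)

    @property
    def n_contractions(self) -> int:
        return self._count(OpKind.CONTRACT)

    @property
    def n_extensions(self) -> int:
        return self._count(OpKind.EXTEND)

    @property
    def total(self) -> int:
        return len(self.ops)

    def to_text(self) -> str:
        """Line-oriented serialization (one op per line)."""
        return "".join(str(op) + "\n" for op in self.ops)

    @classmethod
    def from_text(cls, text: str) -> "EditScript":
        ops = []
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            try:
                kind = OpKind(parts[0])
                if kind is OpKind.FLIP:
                    ops.append(flip_op(int(parts[1]), Label[parts[2].upper()]))
                elif kind is OpKind.CONTRACT:
                    ops.append(contract_op(int(parts[1]), int(parts[2])))
                else:
                    ops.append(extend_op(int(parts[1]),
                                         (int(x) for x in parts[2].split(","))))
            except (KeyError, ValueError, IndexError) as exc:
                raise EditError(f"bad edit script line {lineno}: {line!r}") from exc
        return cls(ops=tuple(ops))


# ---------------------------------------------------------------------------
# Applying operations
# ---------------------------------------------------------------------------

def _check_contraction(tree: LabeledTree, keep: int, remove: int) -> None:
    if keep not in tree or remove not in tree or remove not in tree._adj[keep]:
        raise EditError(f"edge ({keep}, {remove}) is not in the tree")
    if tree.is_leaf(keep) or tree.is_leaf(remove):
        raise EditError(f"cannot contract terminal edge ({keep}, {remove})")
    if tree.label(keep) is not tree.label(remove):
        raise EditError(
            f"edge ({keep}, {remove}) is mixed; a node flip is required "
            "before contracting a mixed edge")


def _check_extension(tree: LabeledTree, node: int, moved: frozenset) -> None:
    if node not in tree or tree.is_leaf(node):
        raise EditError(f"extension target {node} is not an internal node")
    deg = tree.degree(node)
    if len(moved) < 2:
        raise EditError("an extension must move at least 2 neighbors")
    if len(moved) > deg - 2:
        raise EditError(
            f"moving {len(moved)} of {deg} neighbors would leave a degree-2 node")
    if not moved <= set(tree._adj[node]):
        raise EditError(f"{sorted(moved)} are not all neighbors of {node}")


def _check_flip(tree: LabeledTree, node: int, new_label: Label) -> None:
    if node not in tree or tree.is_leaf(node):
        raise EditError(f"flip target {node} is not an internal node")
    if tree.label(node) is new_label:
        raise EditError(f"flip must change the label of node {node}")


def apply_inplace(tree: LabeledTree, op: EditOp) -> Optional[int]:
    """Validate and apply one op in place; returns the new node for EXTEND."""
    if op.kind is OpKind.CONTRACT:
        keep, remove = op.edge
        _check_contraction(tree, keep, remove)
        tree._contract(keep, remove)
        return None
    if op.kind is OpKind.EXTEND:
        _check_extension(tree, op.node, op.moved)
        return tree._extend(op.node, op.moved)
    _check_flip(tree, op.node, op.new_label)
    tree._flip(op.node, op.new_label)
    return None


def apply_contraction(tree: LabeledTree, edge: tuple) -> LabeledTree:
    """Contract an internal equal-label edge; the first endpoint survives."""
    out = tree.copy()
    apply_inplace(out, contract_op(*edge))
    return out


def apply_extension(tree: LabeledTree, node: int, moved_children) -> LabeledTree:
    """Move a neighbor subset of ``node`` onto a new node with the same label."""
    out = tree.copy()
    apply_inplace(out, extend_op(node, moved_children))
    return out


def apply_flip(tree: LabeledTree, node: int, new_label: Label) -> LabeledTree:
    """Assign the other label to an internal node."""
    out = tree.copy()
    apply_inplace(out, flip_op(node, new_label))
    return out


def replay(script: EditScript, source: LabeledTree) -> LabeledTree:
    """Apply a script to (a copy of) ``source``; raise at the first illegal op.

    New nodes created by extensions receive deterministic identifiers, so a
    script recorded against a tree replays identically on an identical copy.
    """
    tree = source.copy()
    for index, op in enumerate(script):
        try:
            apply_inplace(tree, op)
        except EditError as exc:
            raise EditError(f"illegal op at index {index}: {op} ({exc})") from exc
    return tree


# ---------------------------------------------------------------------------
# Random-edit simulator
# ---------------------------------------------------------------------------

FLIP_PROBABILITY = 0.3


def _random_edit_inplace(tree: LabeledTree, rng: random.Random) -> EditOp:
    internal = tree.internal_nodes()
    if not internal:
        raise EditError("random edit requires at least one internal node")

    def do_flip() -> EditOp:
        node = rng.choice(internal)
        op = flip_op(node, tree.label(node).flipped())
        apply_inplace(tree, op)
        return op

    if rng.random() < FLIP_PROBABILITY:
        return do_flip()

    contractible = [e for e in tree.internal_edges()
                    if tree.label(e[0]) is tree.label(e[1])]
    expandable = [v for v in internal if tree.degree(v) > 3]
    pool = [("contract", e) for e in contractible] + \
           [("extend", v) for v in expandable]
    if not pool:
        return do_flip()
    action, target = rng.choice(pool)
    if action == "contract":
        op = contract_op(*target)
    else:
        deg = tree.degree(target)
        size = rng.randint(2, deg - 2)
        moved = frozenset(rng.sample(tree.neighbors(target), size))
        op = extend_op(target, moved)
    apply_inplace(tree, op)
    return op


def random_edit(tree: LabeledTree, rng: random.Random):
    """Draw and apply one random edit; returns ``(op, new_tree)``.

    ``rng`` is the single seedable generator driving all randomness, so a
    fixed seed yields an identical op sequence across runs.
    """
    out = tree.copy()
    op = _random_edit_inplace(out, rng)
    return op, out


def mutate(tree: LabeledTree, k: int, seed=None):
    """Apply ``k`` random edits; returns ``(mutated_tree, EditScript)``.

    ``seed`` may be an int or an existing ``random.Random``.  The returned
    script replays the returned tree from the input tree.
    """
    if k < 0:
        raise ValueError("edit count must be non-negative")
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    out = tree.copy()
    ops = tuple(_random_edit_inplace(out, rng) for _ in range(k))
    return out, EditScript(ops=ops)
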