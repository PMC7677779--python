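# Methods

## Model and assumptions

A labeled tree is a connected acyclic graph on integer node ids with named
degree-1 leaves and a binary event label (`Spe`/`Dup`) on every internal
node. Unrooted trees require every internal node to have degree ≥ 3; a
rooted tree distinguishes one internal node, which may have degree 2. The
label alphabet is fixed at exactly two symbols; labelings are *not*
required to be consistent with any species tree, and intermediate trees on
an edit path need not be biologically feasible — the distance is purely
combinatorial. Branch lengths are parsed and discarded: the distance is a
function of labeled topology only. Tree equality throughout means labeled
isomorphism with fixed leaf names (`oracle.canonical_key`), never node-id
equality.

## Edit operations and closure

Contraction is restricted to internal edges whose endpoints share a label;
extension creates a node copying the extended node's label. The bare
definition of an extension only requires X ⊊ Ch(x) with |X| ≥ 2; this
package additionally enforces |X| ≤ deg(x) − 2, because moving deg − 1
neighbors would leave x with degree 2 and the tree class would not be
closed under edits. With that restriction every operation maps valid
unrooted trees to valid unrooted trees, extension/contraction are mutual
inverses and flips are involutions, so the edit graph is undirected and
the induced distance is a metric (verified exhaustively on the 162-state
five-leaf space in the test suite).

## Classical RF, good/bad edges, decomposition

Bipartitions are canonicalized as the unordered pair of leaf-name sets
with the side containing the globally smallest name first; clades are
leaf-name sets below internal nodes of a rooted tree, with the root clade
and singletons excluded as trivial. Classical RF is the symmetric
difference of these sets; rooted pairs can equivalently be compared after
attaching a shared dummy leaf (default name `__ROOT__`, chosen to avoid
collisions with biological identifiers) to the root, and the equality of
the two routes is a standing test.

An internal edge is *good* iff its bipartition occurs in the other tree.
Maximal bad subtrees are the connected components of internal nodes under
bad edges, including singleton components whose incident edges are all
good. Each component is matched to its counterpart in the other tree by
its boundary — the set of bipartitions of its terminal edges (good
internal edges plus leaf edges); this matching is unique and is a perfect
matching covering all internal nodes of both trees. The decomposition
operates on the trees as given; all preprocessing lives in the heuristic.

## Contract-Tree

Contracting a tree to a star always costs one contraction per internal
edge, so only the flip count matters. Phase 1 contracts every non-mixed
internal edge (rescanning after each merge, since merges create new
incident non-mixed edges); the result is a mixed tree. Phase 2 uses the
fact that a mixed tree needs exactly ⌈diam/2⌉ − 1 flips: starting from a
node v of minimum leaf eccentricity (ecc = ⌈diam/2⌉, a *midpoint*), it
alternately flips v to the common label of its internal neighbors and
contracts all internal edges incident to v; every round reduces ecc(v) by
one. Since a mixed tree is properly 2-colored, the final star label equals
the midpoint's starting label flipped (ecc − 1) times.

Label choice: the implementation enumerates *all* minimum-eccentricity
nodes and derives the achievable final labels from their labels and the
shared flip parity. A tree has two (adjacent) midpoints exactly when its
diameter is odd — in a mixed tree they carry different labels, so both
final labels are achievable; an even diameter forces a single midpoint and
a single final label. (Deriving achievability from the enumerated
midpoints rather than from a diameter-parity rule keeps the code correct
independently of how the parity is stated.) Ties among midpoints are
broken deterministically by smallest node id; a requested
`preferred_final_label` is honoured whenever achievable.

## Methodology 2 and the star path

`methodology2` (i) contracts every non-mixed bad edge of both trees —
each such contraction provably reduces the true distance by exactly 1, so
this preprocessing is always safe; contractions are applied in canonical
sorted-edge order, which fixes the intermediate trees but not the (order
independent) count; (ii) decomposes the reduced trees into matched pairs
of (now mixed) maximal bad subtrees; (iii) contracts both sides of each
pair to stars, measuring each side as a standalone tree whose boundary
edges count as terminal edges, and coordinating the two final labels: the
achievable-label sets of the two sides are intersected, a common label is
used when one exists (preferring `Spe` deterministically on ties), and
otherwise one joining flip per pair is charged; (iv) the second tree's
operations are replayed backwards — contractions become extensions,
flips flip back — through an explicitly maintained node isomorphism, so
the result is a single executable edit script from T to T′. Good edges
are never contracted by this strategy. Its total is at most twice the
true distance.

`star_path_cost` applies Contract-Tree to each whole tree (good edges
included), coordinates the two star labels the same way, and reverses the
second contraction. `labeled_rf_estimate` returns the cheaper of the two
(preferring methodology 2 on ties) and reports both totals; since either
script is a valid path, the estimate is always an upper bound on δ. When
both sides of a pair have odd standalone diameter the joining flip may or
may not be avoidable in an optimal solution; the implementation charges it
without claiming optimality. The bound δ ≤ e + e′ + n (bad edges of each
tree plus internal nodes) is exposed as `naive_upper_bound` and caps the
oracle's default search depth.

## Exact oracle

`exact_distance` is breadth-first search over canonical keys, with an
optional bidirectional (meet-in-the-middle) mode that returns identical
values and is used where many oracle calls are needed; the bidirectional
search keeps expanding until the completed depths of the two sides cover
the best meeting found, which is required for correctness. Canonical keys
are the lexicographic minimum over all display roots of a recursive
serialization with sorted children; leaf names are fixed atoms. Neighbor
enumeration generates every legal flip, contraction and extension and
deduplicates by key (complementary extension subsets of a star produce
isomorphic trees, so the number of distinct neighbors can be smaller than
the number of legal ops). The oracle makes no efficiency claims; the
intended regime is ≤ 7 leaves, where the labeled tree space has at most a
few thousand states.

## Random trees and the mutation protocol

`random_labeled_tree` builds a topology by sequential attachment of each
new leaf to a uniformly random edge (Markovian growth, not uniform over
tree space — the shapes are mildly more balanced than uniform), then
contracts each internal edge independently with probability
`multifurcation_rate`, then assigns independent equiprobable labels. It
stands in for a real reconciled gene-family tree; real trees have
non-uniform shape distributions, correlated duplication clusters and many
more leaves, so passing benchmarks here demonstrate correctness of the
machinery, not calibration on empirical data.

`random_edit` flips a uniformly random internal node with probability 0.3;
the remaining 0.7 is spread uniformly over the union of contractible
internal edges (equal-label endpoints) and expandable nodes (degree > 3).
Two details are simulator conventions not fixed by the protocol: for an
extension, the subset size is drawn uniformly from {2, …, deg − 2} and
then a uniform subset of that size; and when the 0.7-pool is empty (e.g. a
binary fully mixed tree) the edit falls back to a flip, i.e. the flip
probability absorbs the remaining mass. A single seedable `random.Random`
drives all randomness, and `mutate` returns the replayable script of the
edits it applied.

`evaluation_run` applies k = 1 … k_max successive edits per replicate and
records classical RF and the labeled estimate after each edit. The default
benchmark in the test suite uses a 30-leaf binary base tree, k ≤ 10 and 30
replicates — sizes at which the whole suite runs in well under a minute
while the qualitative behaviour (the labeled estimate tracks k much more
closely than label-blind RF, and never falls below RF) is already stable.

## Numerical and determinism choices

* Node ids are allocated by a per-tree counter; copies preserve ids and
  the counter, so recorded edit scripts replay identically on an identical
  copy (extensions re-create the same ids).
* Contraction keeps the first node of the recorded edge; all candidate
  scans (edges, midpoints, components) iterate in sorted order, making
  every algorithm deterministic without any randomness.
* Newick output uses a canonical child order (increasing smallest
  descendant leaf name); rooted trees serialize from the root, unrooted
  trees from the smallest-id internal node, so output is reproducible and
  parse∘write is isomorphism-preserving.
* Degree-2 non-root nodes are rejected at parse time by default; the
  opt-in `suppress_unary` mode removes them and drops their label, but
  refuses when that label conflicts with every adjacent internal node.

## Known limitations

* The estimate is an upper bound; neither strategy is optimal in general
  (optimal paths may interleave contractions and extensions, e.g. via
  NNI-like rearrangements on "safe" edges, which are not implemented), and
  the exact problem's complexity is open.
* Only two labels are supported; multi-label alphabets, edit costs other
  than unit, branch-length-aware RF variants and multilabeled trees
  (repeated leaf names) are out of scope.
* The exact oracle is exponential and refuses large inputs by default in
  the CLI.
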