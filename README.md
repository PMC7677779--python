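# lrfdist — Robinson–Foulds edit distance for event-labeled gene trees

Reconciled gene trees annotate every internal node with an evolutionary
event — a **speciation** or a **duplication**. The classical
Robinson–Foulds (RF) distance compares only topologies, so two trees with
identical shapes but different event annotations are "identical" to it.
`lrfdist` implements the labeled extension of RF for people who compare
inferred gene trees against each other or against curated references
(e.g. orthology benchmarking): distances are lengths of edit scripts built
from three unit-cost operations that respect the labels.

## The model

A labeled tree is a (rooted or unrooted) multifurcating tree on a leaf set
ℒ with a label λ(x) ∈ {Spe, Dup} on every internal node. Three edit
operations are defined:

* **Cont(T, e)** — contract an internal edge e = {x, y} with λ(x) = λ(y);
* **Ext(T, x, X)** — move a neighbor subset X ⊊ Ch(x), |X| ≥ 2, onto a new
  node y with λ(y) = λ(x) (the inverse of a contraction);
* **Flip(x, λ′)** — change λ(x) to the other label.

δ(T, T′) is the minimum number of operations transforming T into T′; it is
a metric, and for uniformly labeled trees it coincides with classical RF
(the symmetric difference |B(T) △ B(T′)| of the non-trivial bipartition
sets). Computing δ exactly in general is an open problem, so the package
provides:

* `contract_tree` — an **optimal** contraction of a tree to a star: after
  free contraction of all non-mixed internal edges, a *mixed* tree (every
  internal edge joins differently labeled nodes) needs exactly
  ⌈diam(T)/2⌉ − 1 flips, realised by alternating flip-and-contract steps
  from a midpoint (a node of minimum leaf eccentricity);
* `methodology2` — a **2-approximation**: contract every non-mixed bad
  edge (each such contraction reduces δ by exactly 1), pair up the maximal
  bad subtrees of the two trees, contract both sides of each pair to stars
  with coordinated labels, and join the paths;
* `star_path_cost` — the alternative global path T → star → T′, which
  contracts good edges too and is sometimes cheaper;
* `labeled_rf_estimate` — the cheaper of the two, with an explicit witness
  `EditScript` that replays T into T′ (so the estimate is always an upper
  bound on δ);
* `exact_distance` — a BFS oracle over the edit graph, exact on small
  trees (≲ 7 leaves);
* `mutate` / `evaluation_run` — the random-edit simulation protocol (flip
  with probability 0.3, otherwise a uniform choice among contractible
  edges and expandable nodes) used to benchmark the estimator.

Trees are read and written as Newick, with labels carried either by
internal node names (`(A,B)Spe`) or NHX duplication tags
(`(A,B)[&&NHX:D=Y]`). Rooted trees are handled through the standard
dummy-leaf construction, under which clade-based RF and split-based RF
agree.

## Worked example

The package ships a deterministic reconstruction of the instance where the
optimal path must contract a *good* (shared) edge: `T` is a speciation hub
carrying three label-alternating chains of six internal nodes (21 leaves,
all 18 internal edges mixed, 9 duplication nodes), `T′` is an
all-speciation tree on the same leaves sharing exactly one split with `T`.

```bash
$ lrf fixtures worked-example --out demo
$ lrf dist demo/T.nwk demo/Tprime.nwk
labeled RF estimate: 42 (6 flips, 18 contractions, 18 extensions; star_path)
classical RF: 34
```

Handling the two bad subtrees of `T` separately costs 9 flips + 17
contractions + 17 extensions = 43 operations (`methodology2`), but
contracting the good edge lets all three chains be handled together —
6 flips + 18 contractions + 18 extensions = 42 (`star_path`), which is the
path the estimate returns; the classical RF distance (17 bad edges per
tree) sees only 34. In Python:

```python
>>> from lrfdist import worked_example_pair, labeled_rf_estimate, replay, canonical_key
>>> pair = worked_example_pair()
>>> report = labeled_rf_estimate(pair.T, pair.T_prime)
>>> report.total, report.method_tag, report.alternatives
(42, 'star_path', {'methodology2': 43, 'star_path': 42})
>>> canonical_key(replay(report.script, pair.T)) == canonical_key(pair.T_prime)
True
```

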