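# Methods

## The model

`kgwalc` classifies nodes (entities) of a knowledge graph by mining
*wildcard walks* that are informative for the class labels. A walk of depth
`l` has the form

    root -> * -> ... -> * -> x        (l - 1 wildcards)

written as the pair `w = (x, l)`: it matches an entity `v` iff some directed
walk of exactly `l` hops starting at `v` ends in a vertex labeled `x`. The
intermediate hops are unconstrained, which lets a single walk capture "an
entity of kind `x` occurs at distance `l`" without committing to the path.

### Graph conversion

A KG is multi-relational; the miner operates on a label-only directed
graph. Every triple `(s, p, o)` becomes three labeled vertices and two
unlabeled edges `s -> p -> o`. The predicate vertex is created *fresh per
triple occurrence* (labels shared, identities not): a single shared vertex
per predicate IRI would splice unrelated triples together and fabricate
walks that do not exist in the KG. Subjects, objects and literals are
shared by string identity; literals are labeled by their lexical form,
blank nodes by their serialization-scoped id. Edges are traversed forward
only. A consequence of the conversion is depth doubling: `k` entity hops in
the original KG correspond to depth `2k` in the converted graph, and odd
depths land on predicate vertices. Mining on converted KGs therefore skips
odd-depth candidates by default (`skip_odd=True`); plain labeled graphs
(the artificial examples) use `skip_odd=False`.

### Neighborhoods and constant-time matching

For each training entity we precompute, by iterated frontier expansion, the
sets `N_i(v)` of labels reachable in *exactly* `i` hops, `i = 1..d`. Walk
containment is then one set-membership test. Frontier expansion enumerates
true walks, not simple paths — vertices may be revisited, so in a 2-cycle a
label recurs at every other depth. Only presence/absence is stored
(sets, not multisets); the splitting criterion consumes nothing else.

### Scoring

A candidate walk `w` splits the training set `D` into `D_f` (found) and
`D_nf` (not found). Its score is the information gain

    IG(D, w) = H(D) - [ |D_f|/|D| H(D_f) + |D_nf|/|D| H(D_nf) ]

with `H` the Shannon entropy of the class proportions. Entropy is reported
in bits (log base 2); the choice of base rescales magnitudes but never
changes a ranking. Degenerate splits (walk found for all entities or none)
score exactly 0. Candidates are the union over the training neighborhoods
of the (label, depth) pairs actually present — argmax-equivalent to
sweeping all graph vertices at all depths, because an unseen walk induces a
degenerate split, and far cheaper (O(d · |V_train| · |V|) to score all
candidates against all training neighborhoods).

Ties between equal-gain walks are broken deterministically: smaller depth
first, then lexicographically smaller end label. Reproducibility demands a
total order; the specific order is a convention.

## The three classifiers

**Decision tree.** Recursive mining: each internal node tests the best walk
of its own partition; found goes left, not-found right. Stop conditions:
node purity, tree depth `max_depth` (`None` = unbounded), node size below
`min_samples`, or no candidate with positive gain (unsplittable impure
nodes occur; they become majority leaves — our choice, with ties to the
lexicographically smallest class). With no pruning, any training set whose
classes have distinct neighborhoods is classified perfectly: each split
with positive gain strictly shrinks both children, so recursion terminates
in pure leaves. Prediction routes by walk containment and returns the
root-to-leaf decisions as a local explanation; trees export to DOT and a
stable nested-record text format.

**Forest.** `n_trees` trees, each optionally grown on a bootstrap resample
of size `|D|` (duplicates enter the entropy counts via repeated labels —
equivalent to instance weights and simpler) and mining each node from a
uniform `vertex_sample` fraction of candidates (ceil of the fraction,
without replacement). Per-tree random streams derive from
`default_rng([seed, tree_index])`, so any tree is reproducible in
isolation. Prediction is majority vote with the same lexicographic tie
rule. Walk importances sum `1/(1 + node_depth)` per occurrence — any
strictly decreasing positional weight expresses "roots matter more"; this
form is simply documented and tested as-is — with raw occurrence counts
reported alongside so a plain root-node census can be read off.

**Feature transform.** One pass ranks all candidates by gain on the full
training set and keeps the top K; entities become K-dimensional binary
presence vectors for any downstream classifier. Scoring against the whole
dataset favors majority-vs-rest splitters on imbalanced data (see the
worked example below). The `per_class` mode counters this: labels are
binarized one-vs-rest per class (ascending class order) and `⌊K/C⌋` walks
mined per class, concatenated, deduplicated keeping first occurrence, and
not topped back up to K. Columns found in exactly one or in all training
rows can be pruned as uninformative. The matrix exports to MatrixMarket
plus a column-metadata TSV; a thin adapter fits scikit-learn's
L1-regularized logistic regression and reports per-walk coefficients for
inspection — the classifier itself is deliberately not reimplemented.

## Synthetic data

The generators define the conditions under which every claim is tested:

* **Toy three-class graph** (`make_fig3_graph`): 8 class-A entities each
  linked to all of five shared hubs "1".."5"; 2 class-B entities linked to
  hub "6"; 2 class-C entities linked to hub "7". Prior entropy
  H(8,2,2) = 1.2516 bits; each majority hub gains 0.9183 bits, each
  minority hub 0.6500 bits. Hence the global transform needs K = 6 walks
  for linear separability (at K = 5 the two minority classes have identical
  all-zero feature rows) while the tree needs only 2: one majority hub at
  the root, one minority hub below it. The exact edge multiset of the
  motivating figure is not published; this construction reproduces the
  stated class sizes, walk families and gain ordering, which is what every
  documented behavior depends on.
* **Planted KGs** (`make_planted_kg`): triples with a class-discriminative
  chain of `depth/2` hops ending in a reserved signal label, present in
  `ceil(penetrance · n_class)` entities of one class and no others, on top
  of class-independent noise (entity→predicate→object triples from small
  noise pools, plus links among noise objects so deeper noise walks exist).
  Chain intermediates are private per carrier, so the signal label itself is
  the only class-discriminative label at any depth. Every entity carries a
  neutral type triple so it exists in the graph even without noise.
  Defaults: 10 entities per class, 2 classes, 3 noise predicates, 10 noise
  objects, 3 noise edges per entity — small enough that mining is
  instantaneous, dense enough that noise candidates exist at all depths.
* **Random graphs** (`make_random_graph`): seeded directed G(n, p) with
  uniform labels; the substrate for oracle-equivalence tests against
  exhaustive walk enumeration (kept to ≲ 30 vertices where enumeration is
  exact and cheap).

What these generators do *not* emulate: the scale (10^4–10^6 triples),
degree heterogeneity, schema structure, or literal-rich content of real
benchmark KGs. Passing tests certify algorithmic correctness — containment
semantics, gain computation, tie-breaking, recovery of planted signal —
not predictive performance on real data.

## Numerical and design choices

* Entropy: exact fractions via `Counter`, `0·log 0 = 0`; gain clamped at 0
  against floating-point negatives.
* Degenerate partitions are represented with `None` sides (datasets are
  non-empty by contract) and score 0.
* Sizes used in the test suite: oracle equivalence over 200 random graphs
  of 8–30 vertices at walk depth ≤ 4; planted-signal recovery over 10 seeds
  at depths 2 and 4 and penetrance 1.0/0.9; the toy example throughout.
* Linear separability (for the smallest-K search) is decided by a
  hard-margin-like linear SVM (`C = 10^6`) reaching training accuracy 1.0.
* Accuracy is what the CLI reports because it is the standard comparison
  metric for this task, but it is skewed by class imbalance; the run log
  carries that caveat, and task-appropriate metrics should be preferred on
  real problems.

## Known limitations

* Walk patterns are exactly "root, wildcards, one terminal label" — no
  partially filled wildcards or subgraph patterns.
* No inverse-edge traversal, OWL reasoning, datatype coercion or quad
  support; IRIs and literals sharing a lexical form collapse to one vertex.
* Neighborhood extraction is recomputed per run (no on-disk cache); at the
  scales this package targets it is not a bottleneck.
* No out-of-bag error estimation or cross-validation harness.
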