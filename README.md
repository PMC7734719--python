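# kgwalc

Interpretable node classification in knowledge graphs by mining
discriminative wildcard walks.

Knowledge graphs encode domain knowledge as `(subject, predicate, object)`
triples. Classifying their entities — which research group a person belongs
to, whether a molecule is carcinogenic, what category a museum artifact
falls in — is usually done with graph embeddings or graph neural networks,
which predict well but explain nothing. `kgwalc` takes the opposite route:
it mines *walk patterns* that are individually informative for the class
labels and builds transparent models out of them. It is aimed at anyone who
needs the model itself to be inspectable, for example in clinical or other
high-stakes settings.

## The method

A *wildcard walk* of depth *l* is the pattern

```
root -> * -> ... -> * -> x        (l − 1 wildcards)
```

written `w = (x, l)`: it matches entity *v* iff some directed walk of
exactly *l* hops from *v* ends in a vertex labeled *x*. The KG is first
flattened — each triple becomes three labeled vertices and two unlabeled
edges `s → p → o`, with a fresh predicate vertex per triple occurrence — so
only vertex labels matter. Precomputing, per entity, the label sets
**N**ᵢ(v) reachable in exactly *i* hops (*i* = 1..*d*) makes each walk
lookup a single set-membership test.

A walk *w* splits the training set *D* into *D_f* (walk found) and *D_nf*
(not found) and is scored by information gain,

```
IG(D, w) = H(D) − [ |D_f|/|D| · H(D_f) + |D_nf|/|D| · H(D_nf) ],
```

with *H* the Shannon entropy of the class labels in bits. Three classifiers
build on the miner:

* **tree** — recursively mine the best walk per partition: a decision tree
  whose every test is a readable pattern;
* **forest** — an ensemble with bootstrap and per-node candidate sampling,
  plus position-weighted walk importances;
* **transform** — one pass keeps the top-K walks and emits binary
  walk-presence feature matrices for any downstream classifier.

See `docs/methods.md` for the full model description and design choices.

## Worked example

The built-in imbalanced three-class graph: 8 class-A entities each linked
to five shared hubs "1".."5", 2 class-B entities linked to hub "6", 2
class-C entities linked to hub "7".

```python
from kgwalc import (make_fig3_graph, extract_neighborhoods, entropy,
                    mine_walks, build_tree, tree_to_text)

graph, data = make_fig3_graph()
nbhs = extract_neighborhoods(graph, data, depth=1)
print(f"prior entropy: {entropy(data.labels):.4f} bits")
for s in mine_walks(data, nbhs, n=7, max_depth=1):
    print(f"{str(s.walk):16s} IG={s.ig:.4f}  found in {s.n_found}/12")
print(tree_to_text(build_tree(data, nbhs, max_walk_depth=1)), end="")
```

prints

```
prior entropy: 1.2516 bits
root -> 1        IG=0.9183  found in 8/12
root -> 2        IG=0.9183  found in 8/12
root -> 3        IG=0.9183  found in 8/12
root -> 4        IG=0.9183  found in 8/12
root -> 5        IG=0.9183  found in 8/12
root -> 6        IG=0.6500  found in 2/12
root -> 7        IG=0.6500  found in 2/12
node walk=('1', 1) ig=0.918296 n=12
  leaf class=A n=8
  node walk=('6', 1) ig=1.000000 n=4
    leaf class=B n=2
    leaf class=C n=2
```

Every majority hub splits the 8 class-A entities from the rest (0.9183
bits of gain); the minority hubs gain less (0.6500 bits) *on the full
dataset*. The tree needs only 2 walks because its second split is scored on
the 4-entity remainder, where `root -> 6` is a perfect 1-bit split. The
single-pass transform, scoring everything globally, must keep all five
majority-hub walks before any minority hub enters: with K = 5 the B and C
entities have identical feature rows, and K = 6 is the smallest feature set
that separates all three classes. Its `per_class` mode (one-vs-rest mining
per class) exists precisely to avoid this.

## Command line

```
kgwalc fixtures fig3 --out example/
kgwalc tree  --graph example/graph.tsv --format edgelist \
             --labels example/labels.tsv --depth 1 --out run/
kgwalc mine  --graph data.nt --labels train.tsv --depth 6 --n 25 --out run/
kgwalc forest    ... --n-trees 25 --vertex-sample 0.5 --bootstrap
kgwalc transform ... --k 10000 --mode per_class --prune
```

RDF inputs (N-Triples/Turtle) are converted with the depth-doubling
convention — *k* entity hops = depth 2*k*, odd depths skipped by default —
and support an exclusion list of label-leaking predicates. Each run writes
its artifacts (walks/importances TSV, DOT tree, MTX matrices, predictions
with accuracy) plus a `run.log` with the effective configuration and seed;
identical config and seed give identical artifacts.

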