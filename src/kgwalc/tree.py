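"""Decision trees whose internal nodes test the presence of a mined walk.

Induction mirrors classic information-gain tree learning, except that the
search for the best feature/threshold split is replaced by mining the best
wildcard walk on the node's partition of the training data.  The entities in
which the walk is found go to the left ("found") child, the rest to the
right ("not found") child, and mining recurses on each side.

Growth stops at a node when it is pure, when the tree reaches ``max_depth``,
when fewer than ``min_samples`` entities remain, or when no candidate walk
has positive gain (an unsplittable impure node); the node then becomes a
leaf predicting its majority class, ties resolving to the lexicographically
smallest label for determinism.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Optional, Union

import numpy as np

from .kg_io import Dataset
from .neighborhood import Neighborhood, Walk, contains_walk
from .walk_mining import mine_walks

__all__ = ["Leaf", "InternalNode", "WalkTree", "build_tree", "predict",
           "explain", "export_dot", "tree_to_text", "n_internal_nodes",
           "tree_walks"]


@dataclass(frozen=True)
class Leaf:
    class_label: object
    n_samples: int


@dataclass(frozen=True)
class InternalNode:
    walk: Walk
    ig: float
    found_child: "WalkTree"
    not_found_child: "WalkTree"
    n_samples: int


WalkTree = Union[Leaf, InternalNode]


def _majority(labels) -> object:
    counts = Counter(labels)
    best = max(counts.values())
    return min(k for k, c in counts.items() if c == best)


def build_tree(data: Dataset,
               nbhs: Mapping[object, Neighborhood],
               max_walk_depth: int,
               max_depth: Optional[int] = None,
               min_samples: int = 1,
               skip_odd: bool = False,
               vertex_sample: float = 1.0,
               rng: Optional[np.random.Generator] = None,
               _cur_depth: int = 0) -> WalkTree:
    """Recursively mine maximum-gain walks to induce a decision tree.

    Parameters
    ----------
    max_walk_depth : maximal depth of the mined walks (graph hops).
    max_depth : maximal tree depth; ``None`` grows until leaves are pure.
    min_samples : a node with fewer entities becomes a leaf (pre-pruning).
    vertex_sample : fraction of walk candidates scored at each node; 1.0
        with no bootstrap is the single-tree configuration.
    """
    if len(data) == 0:  # Dataset forbids this, but guard the recursion
        raise ValueError("cannot build a tree from an empty dataset")
    labels = data.labels
    pure = len(set(labels)) == 1
    depth_stop = max_depth is not None and _cur_depth >= max_depth
    size_stop = len(data) < min_samples
    if pure or depth_stop or size_stop:
        return Leaf(class_label=_majority(labels), n_samples=len(data))
    best = mine_walks(data, nbhs, n=1, max_depth=max_walk_depth,
                      skip_odd=skip_odd, candidate_fraction=vertex_sample,
                      rng=rng)
    if not best or best[0].ig <= 0.0:
        return Leaf(class_label=_majority(labels), n_samples=len(data))
    sw = best[0]
    f_idx = [i for i, v in enumerate(data.entities)
             if contains_walk(nbhs[v], sw.walk)]
    f_set = set(f_idx)
    nf_idx = [i for i in range(len(data)) if i not in f_set]
    kwargs = dict(max_walk_depth=max_walk_depth, max_depth=max_depth,
                  min_samples=min_samples, skip_odd=skip_odd,
                  vertex_sample=vertex_sample, rng=rng,
                  _cur_depth=_cur_depth + 1)
    return InternalNode(
        walk=sw.walk,
        ig=sw.ig,
        found_child=build_tree(data.subset(f_idx), nbhs, **kwargs),
        not_found_child=build_tree(data.subset(nf_idx), nbhs, **kwargs),
        n_samples=len(data),
    )


def predict(tree: WalkTree, nbh: Neighborhood):
    """Route a neighborhood to a leaf; returns the leaf's class label."""
    label, _ = explain(tree, nbh)
    return label


def explain(tree: WalkTree, nbh: Neighborhood):
    """Predict and return the root-to-leaf path as a local explanation.

    Returns ``(class_label, path)`` where ``path`` is the list of
    ``(walk, found)`` decisions taken at each internal node.
    """
    path: list[tuple[Walk, bool]] = []
    node = tree
    while isinstance(node, InternalNode):
        found = contains_walk(nbh, node.walk)
        path.append((node.walk, found))
        node = node.found_child if found else node.not_found_child
    return node.class_label, path


def n_internal_nodes(tree: WalkTree) -> int:
    if isinstance(tree, Leaf):
        return 0
    return (1 + n_internal_nodes(tree.found_child)
            + n_internal_nodes(tree.not_found_child))


def tree_walks(tree: WalkTree, depth: int = 0):
    """Yield ``(walk, ig, node_depth)`` for every internal node, preorder."""
    if isinstance(tree, InternalNode):
        yield tree.walk, tree.ig, depth
        yield from tree_walks(tree.found_child, depth + 1)
        yield from tree_walks(tree.not_found_child, depth + 1)


def export_dot(tree: WalkTree) -> str:
    """Render the tree as a DOT digraph.

    Internal nodes display the walk as ``root -> * ... * -> label`` with
    ``depth - 1`` wildcard hops; edges are annotated ``found`` /
    ``not found``; leaves show class and sample count.
    """
    lines = ["digraph WalkTree {", '  node [shape=box];']
    counter = [0]

    def emit(node) -> str:
        nid = f"n{counter[0]}"
        counter[0] += 1
        if isinstance(node, Leaf):
            lines.append(
                f'  {nid} [label="{node.class_label}\\n'
                f'n={node.n_samples}", shape=ellipse];'
            )
        else:
            lines.append(
                f'  {nid} [label="{node.walk}\\nIG={node.ig:.4f} bits  '
                f'n={node.n_samples}"];'
            )
            fid = emit(node.found_child)
            nfid = emit(node.not_found_child)
            lines.append(f'  {nid} -> {fid} [label="found"];')
            lines.append(f'  {nid} -> {nfid} [label="not found"];')
        return nid

    emit(tree)
    lines.append("}")
    return "\n".join(lines) + "\n"


def tree_to_text(tree: WalkTree, indent: int = 0) -> str:
    """Nested-record text serialization, stable for identical trees."""
    pad = "  " * indent
    if isinstance(tree, Leaf):
        return f"{pad}leaf class={tree.class_label} n={tree.n_samples}\n"
    out = (f"{pad}node walk=({tree.walk.end_label!r}, {tree.walk.depth}) "
           f"ig={tree.ig:.6f} n={tree.n_samples}\n")
    out += tree_to_text(tree.found_child, indent + 1)
    out += tree_to_text(tree.not_found_child, indent + 1)
    return out
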