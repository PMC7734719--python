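"""Ensembles of walk trees: bootstrap + per-node candidate sampling.

Each tree is grown on a bootstrap resample of the training entities
(optional) and, at every internal node, mines its split from a random
``vertex_sample`` fraction of the walk candidates.  Bootstrap duplicates
carry multiplicity straight into the entropy counts by repeating entities
in the per-tree dataset.  Prediction is a majority vote, ties resolving to
the lexicographically smallest class.

Interpretability survives aggregation through walk importances: each
occurrence of a walk at an internal node contributes ``1 / (1 + node_depth)``
to its score, so a walk at a root (depth 0) counts 1.0 and deeper, less
influential placements count less; raw occurrence counts are reported
alongside.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .kg_io import Dataset
from .neighborhood import Neighborhood, Walk
from .tree import WalkTree, build_tree, predict, tree_walks

__all__ = ["ForestConfig", "WalkForest", "build_forest", "predict_forest",
           "walk_importances", "importances_to_tsv"]


@dataclass(frozen=True)
class ForestConfig:
    n_trees: int = 10
    bootstrap: bool = True
    vertex_sample: float = 0.5
    max_walk_depth: int = 2
    max_depth: Optional[int] = None
    min_samples: int = 1
    skip_odd: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not (0.0 < self.vertex_sample <= 1.0):
            raise ValueError("vertex_sample must be in (0, 1]")


@dataclass
class WalkForest:
    trees: list  # list[WalkTree]
    config: ForestConfig = field(default_factory=ForestConfig)


def _tree_rng(seed: int, index: int) -> np.random.Generator:
    # per-tree streams derive deterministically from (master seed, index)
    return np.random.default_rng([seed, index])


def build_forest(data: Dataset,
                 nbhs: Mapping[object, Neighborhood],
                 config: ForestConfig) -> WalkForest:
    """Grow ``config.n_trees`` walk trees, each independently reproducible.

    With ``n_trees=1, bootstrap=False, vertex_sample=1.0`` the single tree
    is structurally identical to :func:`kgwalc.tree.build_tree`'s output.
    """
    trees: list[WalkTree] = []
    for i in range(config.n_trees):
        rng = _tree_rng(config.seed, i)
        if config.bootstrap:
            idx = rng.integers(0, len(data), size=len(data))
            tree_data = data.subset(idx)
        else:
            tree_data = data
        trees.append(build_tree(
            tree_data, nbhs,
            max_walk_depth=config.max_walk_depth,
            max_depth=config.max_depth,
            min_samples=config.min_samples,
            skip_odd=config.skip_odd,
            vertex_sample=config.vertex_sample,
            rng=rng,
        ))
    return WalkForest(trees=trees, config=config)


def predict_forest(forest: WalkForest, nbh: Neighborhood):
    """Majority vote over per-tree predictions; ties go to the smallest label."""
    votes = Counter(predict(t, nbh) for t in forest.trees)
    best = max(votes.values())
    return min(k for k, c in votes.items() if c == best)


def walk_importances(forest: WalkForest) -> list[tuple[Walk, float, int]]:
    """Position-weighted walk usage across the ensemble.

    Returns ``(walk, score, count)`` triples sorted by score descending,
    ties by (depth asc, label asc).  ``score`` sums ``1 / (1 + node_depth)``
    over occurrences; ``count`` is the raw number of occurrences, matching
    a plain root-node census when trees are inspected at depth 0 only.
    """
    scores: dict[Walk, float] = {}
    counts: dict[Walk, int] = {}
    for tree in forest.trees:
        for walk, _ig, depth in tree_walks(tree):
            scores[walk] = scores.get(walk, 0.0) + 1.0 / (1 + depth)
            counts[walk] = counts.get(walk, 0) + 1
    ranked = [(w, scores[w], counts[w]) for w in scores]
    ranked.sort(key=lambda t: (-t[1], t[0].depth, t[0].end_label))
    return ranked


def importances_to_tsv(ranked, path) -> None:
    """Serialize importances as TSV: end_label, depth, score, count."""
    pd.DataFrame(
        [(w.end_label, w.depth, s, c) for w, s, c in ranked],
        columns=["end_label", "depth", "score", "count"],
    ).to_csv(path, sep="\t", index=False)
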