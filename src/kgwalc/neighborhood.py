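"""Depth-indexed neighborhoods: the data structure behind constant-time walks.

A wildcard walk ``(x, l)`` — ``root -> * -> ... -> * -> x`` with ``l - 1``
wildcards — matches an entity iff some directed walk of length exactly ``l``
from the entity ends at a vertex labeled ``x``.  Precomputing, for each
entity, the set of labels reachable in exactly ``i`` hops for every
``i = 1..d`` turns that match into a single set-membership test.

Reachability is computed by iterated frontier expansion
(``frontier_0 = {root}``, ``frontier_{i+1} = successors(frontier_i)``), so
walks may revisit vertices: in a 2-cycle ``a <-> b`` the label of ``b`` is
reachable from ``a`` at every odd depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .kg_io import Dataset, LabeledGraph

__all__ = ["Walk", "Neighborhood", "extract_neighborhood",
           "extract_neighborhoods", "contains_walk"]


@dataclass(frozen=True, order=True)
class Walk:
    """Wildcard walk ``root -> *^(depth-1) -> end_label``, sorted by (depth, label)."""

    depth: int
    end_label: str

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("walk depth must be >= 1")

    def __str__(self) -> str:
        hops = ["root"] + ["*"] * (self.depth - 1) + [self.end_label]
        return " -> ".join(hops)


@dataclass
class Neighborhood:
    """Per-depth label sets ``N_i(root)`` for ``i = 1..max_depth``."""

    root: object
    max_depth: int
    level_labels: Mapping[int, frozenset]

    def __post_init__(self):
        for i in range(1, self.max_depth + 1):
            if i not in self.level_labels:
                raise ValueError(f"level_labels missing depth {i}")


def extract_neighborhood(graph: LabeledGraph, root, depth: int) -> Neighborhood:
    """Breadth-first frontier expansion from ``root`` for ``depth`` levels.

    ``level_labels[i]`` holds the labels of all vertices reachable by a
    directed walk of length exactly ``i``; a label may occur at several
    depths and level sets may be empty.
    """
    if root not in graph:
        raise KeyError(f"root {root!r} not in graph")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    levels: dict[int, frozenset] = {}
    frontier = {root}
    for i in range(1, depth + 1):
        nxt = set()
        for u in frontier:
            nxt.update(graph.successors(u))
        levels[i] = frozenset(graph.label_of(v) for v in nxt)
        frontier = nxt
    return Neighborhood(root=root, max_depth=depth, level_labels=levels)


def extract_neighborhoods(graph: LabeledGraph, data: Dataset,
                          depth: int) -> dict:
    """Neighborhoods for every (distinct) entity of a dataset."""
    return {v: extract_neighborhood(graph, v, depth)
            for v in dict.fromkeys(data.entities)}


def contains_walk(nbh: Neighborhood, walk: Walk) -> bool:
    """Constant-time test whether the walk matches the neighborhood's root.

    Fixed-depth semantics: the end label must appear at *exactly*
    ``walk.depth`` hops, not at most.
    """
    if walk.depth > nbh.max_depth:
        raise ValueError(
            f"neighborhood of depth {nbh.max_depth} too shallow for "
            f"walk of depth {walk.depth}"
        )
    return walk.end_label in nbh.level_labels[walk.depth]
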