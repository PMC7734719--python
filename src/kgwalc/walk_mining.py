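"""Information-gain scoring and mining of discriminative wildcard walks.

A candidate walk ``w`` splits a training set ``D`` into the entities whose
neighborhood contains it (``D_f``) and those whose neighborhood does not
(``D_nf``).  Its score is the information gain

    IG(D, w) = H(D) - ( |D_f|/|D| * H(D_f) + |D_nf|/|D| * H(D_nf) )

with ``H`` the Shannon entropy of the class labels in bits (log base 2; the
base only fixes reported magnitudes, ranking is base-invariant).  Mining
returns the ``n`` candidates of highest gain under a deterministic total
order: gain descending, then walk depth ascending, then end label ascending.

The candidate space is the union over the training neighborhoods of the
(label, depth) pairs actually present.  A walk found in no training
neighborhood induces the degenerate partition (empty ``D_f``) and scores 0,
so restricting candidates this way is argmax-equivalent to sweeping all
graph vertices at all depths, at a fraction of the cost.

On graphs obtained from triple conversion, odd depths land on per-occurrence
predicate vertices; ``skip_odd=True`` prunes those candidates (``k`` entity
hops in the original KG correspond to depth ``2k`` here).  For plain labeled
graphs use ``skip_odd=False``.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .kg_io import Dataset
from .neighborhood import Neighborhood, Walk, contains_walk

__all__ = ["ScoredWalk", "Partition", "entropy", "partition", "info_gain",
           "enumerate_candidates", "mine_walks", "walks_to_tsv"]


@dataclass(frozen=True)
class ScoredWalk:
    """A walk with its information gain (bits) and training support."""

    walk: Walk
    ig: float
    n_found: int


@dataclass
class Partition:
    """Found / not-found split of a dataset induced by one walk."""

    found: Optional[Dataset]
    not_found: Optional[Dataset]


def entropy(labels: Sequence) -> float:
    """Shannon entropy of a label vector in bits, with 0*log(0) = 0."""
    if len(labels) == 0:
        raise ValueError("entropy of an empty label vector is undefined")
    n = len(labels)
    return -sum(c / n * math.log2(c / n) for c in Counter(labels).values())


def partition(data: Dataset, walk: Walk,
              nbhs: Mapping[object, Neighborhood]) -> Partition:
    """Split ``data`` by walk presence, preserving dataset order.

    Each side is ``None`` when empty (``Dataset`` is non-empty by contract).
    """
    f_idx, nf_idx = [], []
    for i, v in enumerate(data.entities):
        if v not in nbhs:
            raise KeyError(f"no neighborhood for entity {v!r}")
        (f_idx if contains_walk(nbhs[v], walk) else nf_idx).append(i)
    return Partition(
        found=data.subset(f_idx) if f_idx else None,
        not_found=data.subset(nf_idx) if nf_idx else None,
    )


def info_gain(data: Dataset, walk: Walk,
              nbhs: Mapping[object, Neighborhood]) -> float:
    """Information gain of splitting ``data`` on walk presence, in bits.

    Degenerate partitions (walk found for all entities or for none) gain
    nothing and return exactly 0.0.
    """
    part = partition(data, walk, nbhs)
    if part.found is None or part.not_found is None:
        return 0.0
    n = len(data)
    h_cond = (len(part.found) / n * entropy(part.found.labels)
              + len(part.not_found) / n * entropy(part.not_found.labels))
    return max(0.0, entropy(data.labels) - h_cond)


def enumerate_candidates(nbhs: Mapping[object, Neighborhood],
                         max_depth: int,
                         skip_odd: bool = False) -> set[Walk]:
    """Union of (label, depth) pairs present in any training neighborhood.

    With ``skip_odd`` only even depths are kept — the entity positions of a
    converted knowledge graph.
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    cands: set[Walk] = set()
    for nbh in nbhs.values():
        top = min(max_depth, nbh.max_depth)
        for depth in range(1, top + 1):
            if skip_odd and depth % 2 == 1:
                continue
            for label in nbh.level_labels[depth]:
                cands.add(Walk(depth=depth, end_label=label))
    return cands


def _score_candidates(data: Dataset, nbhs, candidates) -> list[ScoredWalk]:
    scored = []
    for w in candidates:
        part = partition(data, w, nbhs)
        n_found = len(part.found) if part.found is not None else 0
        if part.found is None or part.not_found is None:
            ig = 0.0
        else:
            n = len(data)
            h_cond = (len(part.found) / n * entropy(part.found.labels)
                      + len(part.not_found) / n * entropy(part.not_found.labels))
            ig = max(0.0, entropy(data.labels) - h_cond)
        scored.append(ScoredWalk(walk=w, ig=ig, n_found=n_found))
    return scored


def mine_walks(data: Dataset,
               nbhs: Mapping[object, Neighborhood],
               n: int = 1,
               max_depth: int = 2,
               skip_odd: bool = False,
               candidate_fraction: float = 1.0,
               rng: Optional[np.random.Generator] = None) -> list[ScoredWalk]:
    """Mine the ``n`` most informative walks up to ``max_depth``.

    ``candidate_fraction < 1`` scores only a uniform sample (without
    replacement, drawn from ``rng``) of the candidates — the per-node
    ``vertex_sample`` used when growing forest trees.  Ties are broken by
    (depth asc, end label asc); fewer than ``n`` results are returned when
    there are fewer candidates.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 < candidate_fraction <= 1.0):
        raise ValueError("candidate_fraction must be in (0, 1]")
    candidates = sorted(enumerate_candidates(nbhs, max_depth, skip_odd))
    if candidate_fraction < 1.0 and candidates:
        if rng is None:
            raise ValueError("candidate_fraction < 1 requires an rng")
        k = math.ceil(candidate_fraction * len(candidates))
        idx = rng.choice(len(candidates), size=k, replace=False)
        candidates = [candidates[i] for i in sorted(idx)]
    scored = _score_candidates(data, nbhs, candidates)
    scored.sort(key=lambda s: (-s.ig, s.walk.depth, s.walk.end_label))
    return scored[:n]


def walks_to_tsv(scored: Sequence[ScoredWalk], path) -> None:
    """Serialize mined walks as TSV: end_label, depth, ig_bits, n_found."""
    pd.DataFrame(
        [(s.walk.end_label, s.walk.depth, s.ig, s.n_found) for s in scored],
        columns=["end_label", "depth", "ig_bits", "n_found"],
    ).to_csv(path, sep="\t", index=False)
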