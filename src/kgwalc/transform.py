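"""Single-pass top-K walk mining and binary feature matrices.

Instead of recursive partitioning, the feature transform ranks *all* walk
candidates by information gain on the full training set in one pass and
keeps the K best.  Each entity then becomes a K-dimensional binary vector
whose j-th entry flags the presence of walk j in its neighborhood; any
downstream classifier can consume the matrix.

Scoring against the whole dataset has a known pathology on imbalanced data:
walks separating the majority class from everyone else can crowd out the
walks that distinguish the minority classes, so more features are needed
than a tree would use.  The per-class mode counters this by binarizing the
labels one-vs-rest and mining ``K / C`` walks per class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .kg_io import Dataset
from .neighborhood import Neighborhood, Walk, contains_walk
from .walk_mining import mine_walks

__all__ = ["WalkFeatureMatrix", "mine_top_k", "featurize", "prune_columns",
           "export_matrix", "l1_logistic_coefficients"]


@dataclass
class WalkFeatureMatrix:
    """Binary walk-presence matrix: rows are entities, columns are walks."""

    walks: list  # list[Walk], column order
    entities: list  # row order
    values: np.ndarray  # shape (n_entities, n_walks), dtype uint8

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.uint8)
        expected = (len(self.entities), len(self.walks))
        if self.values.shape != expected:
            raise ValueError(f"matrix shape {self.values.shape} != {expected}")


def mine_top_k(data: Dataset,
               nbhs: Mapping[object, Neighborhood],
               k: int,
               max_depth: int,
               mode: str = "global",
               skip_odd: bool = False,
               rng: Optional[np.random.Generator] = None) -> list[Walk]:
    """Mine the K highest-gain walks in a single pass.

    mode="global": top-K by gain on the full multi-class dataset; exactly
    the K-prefix of the full gain-sorted candidate list.

    mode="per_class": for each class (ascending order) the labels are
    binarized one-vs-rest and the top ``K // C`` walks mined; results are
    concatenated and deduplicated keeping first occurrence, without topping
    back up to K.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if mode == "global":
        scored = mine_walks(data, nbhs, n=k, max_depth=max_depth,
                            skip_odd=skip_odd, rng=rng)
        walks = [s.walk for s in scored]
        if len(walks) < k:
            warnings.warn(f"only {len(walks)} candidates available for k={k}",
                          stacklevel=2)
        return walks
    if mode == "per_class":
        classes = data.classes
        if k < len(classes):
            raise ValueError("per_class mode requires k >= number of classes")
        per = k // len(classes)
        walks: list[Walk] = []
        for cls in classes:
            binarized = Dataset(
                list(data.entities),
                [1 if y == cls else 0 for y in data.labels],
            )
            scored = mine_walks(binarized, nbhs, n=per, max_depth=max_depth,
                                skip_odd=skip_odd, rng=rng)
            walks.extend(s.walk for s in scored)
        return list(dict.fromkeys(walks))
    raise ValueError(f"unknown mode {mode!r}; use 'global' or 'per_class'")


def featurize(walks: Sequence[Walk],
              entities: Sequence,
              nbhs: Mapping[object, Neighborhood]) -> WalkFeatureMatrix:
    """Evaluate walk presence for each entity; columns follow ``walks``.

    Test entities are featurized against the columns mined on training data,
    so train and test matrices line up.
    """
    values = np.zeros((len(entities), len(walks)), dtype=np.uint8)
    for i, v in enumerate(entities):
        if v not in nbhs:
            raise KeyError(f"no neighborhood for entity {v!r}")
        for j, w in enumerate(walks):
            values[i, j] = contains_walk(nbhs[v], w)
    return WalkFeatureMatrix(walks=list(walks), entities=list(entities),
                             values=values)


def prune_columns(matrix: WalkFeatureMatrix) -> WalkFeatureMatrix:
    """Drop uninformative columns: walks found in exactly 1 or in all rows.

    A walk present everywhere (or all but nowhere) cannot split the training
    set usefully.  Returns a new matrix; the dropped walks are recorded on
    it as ``dropped_walks``.
    """
    sums = matrix.values.sum(axis=0)
    n = len(matrix.entities)
    keep = [j for j, s in enumerate(sums) if s != 1 and s != n]
    pruned = WalkFeatureMatrix(
        walks=[matrix.walks[j] for j in keep],
        entities=list(matrix.entities),
        values=matrix.values[:, keep] if keep else
        np.zeros((n, 0), dtype=np.uint8),
    )
    pruned.dropped_walks = [matrix.walks[j] for j in range(len(matrix.walks))
                            if j not in set(keep)]
    return pruned


def export_matrix(matrix: WalkFeatureMatrix, mtx_path, walks_tsv_path,
                  ig_bits: Optional[Sequence[float]] = None) -> None:
    """Write the matrix as MatrixMarket plus a column-metadata TSV."""
    scipy.io.mmwrite(str(mtx_path), scipy.sparse.csr_matrix(matrix.values))
    meta = {"end_label": [w.end_label for w in matrix.walks],
            "depth": [w.depth for w in matrix.walks]}
    if ig_bits is not None:
        meta["ig_bits"] = list(ig_bits)
    pd.DataFrame(meta).to_csv(walks_tsv_path, sep="\t", index=False)


def l1_logistic_coefficients(matrix: WalkFeatureMatrix, labels: Sequence,
                             C: float = 1.0):
    """Fit an L1-regularized logistic regression and report per-walk weights.

    Thin adapter over scikit-learn for the coefficient-inspection workflow:
    a positive coefficient means finding the walk pushes the prediction
    toward the corresponding class.  Returns a DataFrame with one row per
    (class, walk) sorted by |coefficient| descending.
    """
    from sklearn.linear_model import LogisticRegression

    clf = LogisticRegression(l1_ratio=1.0, solver="liblinear", C=C)
    clf.fit(matrix.values, list(labels))
    rows = []
    for ci, cls in enumerate(clf.classes_ if clf.coef_.shape[0] > 1
                             else [clf.classes_[1]]):
        for j, w in enumerate(matrix.walks):
            rows.append((cls, str(w), w.depth, clf.coef_[ci, j]))
    df = pd.DataFrame(rows, columns=["class", "walk", "depth", "coef"])
    return df.reindex(df["coef"].abs().sort_values(ascending=False).index)
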