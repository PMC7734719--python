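"""Deterministic synthetic graphs for exercising every part of the miner.

Three generators:

* :func:`make_fig3_graph` — the small imbalanced three-class example used
  throughout the documentation: 8 majority-class entities each linked to
  five shared hub nodes, and two minority classes of 2 entities linked to
  one private hub each.  Single-pass top-K mining on it needs 6 walks for
  perfect separation while the decision tree needs only 2 — the motivating
  pathology for the per-class transform mode.
* :func:`make_planted_kg` — random knowledge graphs (emitted as triples)
  with class-discriminative walks planted at chosen even depths and
  penetrance, on top of class-independent noise triples.
* :func:`make_random_graph` — seeded Erdős–Rényi-style labeled digraphs,
  the substrate for brute-force oracle-equivalence tests.

All generators are fully determined by their arguments (and seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .kg_io import Dataset, LabeledGraph, Triple, entity_vertex_id

__all__ = ["PlantedWalkSpec", "PlantedKGSpec", "make_fig3_graph",
           "make_planted_kg", "make_random_graph", "write_fig3_files"]


def make_fig3_graph() -> tuple[LabeledGraph, Dataset]:
    """The imbalanced three-class toy graph.

    Classes: "A" (8 entities, each with an edge to every hub "1".."5"),
    "B" (2 entities linked to hub "6"), "C" (2 entities linked to hub "7").
    Entities are labeled by their own names; 12 training entities plus the
    7 hub nodes.
    """
    lg = LabeledGraph()
    for hub in "1234567":
        lg.add_vertex(entity_vertex_id(hub), hub)
    entities, labels = [], []

    def add_entities(prefix: str, cls: str, count: int, hubs: Sequence[str]):
        for i in range(count):
            name = f"{prefix}{i}"
            vid = entity_vertex_id(name)
            lg.add_vertex(vid, name)
            for hub in hubs:
                lg.add_edge(vid, entity_vertex_id(hub))
            entities.append(vid)
            labels.append(cls)

    add_entities("a", "A", 8, list("12345"))
    add_entities("b", "B", 2, ["6"])
    add_entities("c", "C", 2, ["7"])
    return lg, Dataset(entities, labels)


@dataclass(frozen=True)
class PlantedWalkSpec:
    """One discriminative signal: entities of ``class_index`` get a chain of
    ``depth // 2`` triples ending in an object labeled ``signal_label``."""

    class_index: int
    depth: int  # hops in the converted graph; must be even
    signal_label: str
    penetrance: float = 1.0

    def __post_init__(self):
        if self.depth % 2 != 0 or self.depth < 2:
            raise ValueError("planted walk depth must be a positive even "
                             "number of converted-graph hops")
        if not (0.0 < self.penetrance <= 1.0):
            raise ValueError("penetrance must be in (0, 1]")


@dataclass(frozen=True)
class PlantedKGSpec:
    """Recipe for a synthetic KG with planted class-discriminative walks."""

    n_entities_per_class: int = 10
    n_classes: int = 2
    planted: tuple = (PlantedWalkSpec(class_index=1, depth=2,
                                      signal_label="signal"),)
    n_noise_predicates: int = 3
    n_noise_objects: int = 10
    edges_per_entity: int = 3
    seed: int = 0


def make_planted_kg(spec: PlantedKGSpec) -> tuple[list[Triple], Dataset]:
    """Emit triples realizing the spec, plus the entity/label dataset.

    After triple conversion, each planted walk ``(signal_label, depth)`` is
    present in exactly ``ceil(penetrance * n_class)`` entities of its class
    and in no entity of any other class: the chain's intermediate nodes and
    signal object are private to the plant, and noise objects never link
    back into chains.  Noise triples (entity -> noise predicate -> noise
    object, plus links among noise objects) are class-independent.
    """
    rng = np.random.default_rng(spec.seed)
    noise_preds = [f"np{j}" for j in range(spec.n_noise_predicates)]
    noise_objs = [f"no{j}" for j in range(spec.n_noise_objects)]
    reserved = set(noise_preds) | set(noise_objs) | {"hasType", "Entity"}
    for p in spec.planted:
        if p.signal_label in reserved:
            raise ValueError(
                f"signal label {p.signal_label!r} collides with another "
                "generated label"
            )
        reserved.add(p.signal_label)

    entities: list[str] = []
    labels: list[str] = []
    for c in range(spec.n_classes):
        for i in range(spec.n_entities_per_class):
            entities.append(f"c{c}_e{i}")
            labels.append(f"class{c}")

    triples: list[Triple] = []
    # planted chains: e -> sp -> mid -> sp -> ... -> signal object; the
    # intermediate nodes are private per carrier so that only the signal
    # label itself is class-discriminative at any depth
    for pi, plant in enumerate(spec.planted):
        n_hops = plant.depth // 2
        pred = f"sp{pi}"
        cls_entities = [e for e, y in zip(entities, labels)
                        if y == f"class{plant.class_index}"]
        n_carriers = int(np.ceil(plant.penetrance * len(cls_entities)))
        for e in cls_entities[:n_carriers]:
            chain = [e] + [f"mid_p{pi}_{e}_{j}" for j in range(n_hops - 1)]
            chain.append(plant.signal_label)
            for j in range(len(chain) - 1):
                triples.append(Triple(chain[j], pred, chain[j + 1]))
    # every entity carries a type triple, so it is present in the converted
    # graph even without noise; the shared label is class-independent and
    # induces only degenerate (zero-gain) walk candidates
    for e in entities:
        triples.append(Triple(e, "hasType", "Entity"))
    # class-independent background noise
    for e in entities:
        for _ in range(spec.edges_per_entity):
            triples.append(Triple(e,
                                  noise_preds[rng.integers(len(noise_preds))],
                                  noise_objs[rng.integers(len(noise_objs))]))
    if spec.n_noise_objects > 1:
        for j, o in enumerate(noise_objs):
            other = noise_objs[(j + 1 + rng.integers(len(noise_objs) - 1))
                               % len(noise_objs)]
            triples.append(Triple(o, noise_preds[rng.integers(len(noise_preds))],
                                  other))
    return triples, Dataset([entity_vertex_id(e) for e in entities], labels)


def make_random_graph(n_vertices: int, n_labels: int, edge_prob: float,
                      seed: int = 0) -> LabeledGraph:
    """Seeded directed G(n, p) graph with labels drawn uniformly."""
    if not (0.0 <= edge_prob <= 1.0):
        raise ValueError("edge_prob must be in [0, 1]")
    if n_labels < 1:
        raise ValueError("n_labels must be >= 1")
    g = nx.gnp_random_graph(n_vertices, edge_prob, seed=seed, directed=True)
    rng = np.random.default_rng(seed)
    lg = LabeledGraph()
    for v in range(n_vertices):
        lg.add_vertex(v, f"L{rng.integers(n_labels)}")
    for u, v in g.edges:
        lg.add_edge(u, v)
    return lg


def write_fig3_files(out_dir) -> None:
    """Write the toy graph as edge-list TSV + labels TSV under ``out_dir``."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lg, data = make_fig3_graph()
    edges = [(lg.label_of(u), lg.label_of(v)) for u, v in sorted(lg.edges)]
    pd.DataFrame(edges, columns=["src", "dst"]).to_csv(
        out / "graph.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"entity": [lg.label_of(v) for v in data.entities],
         "label": data.labels},
    ).to_csv(out / "labels.tsv", sep="\t", index=False)
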