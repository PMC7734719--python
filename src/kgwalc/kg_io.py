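"""Reading RDF input and converting it to the label-only graph the miner uses.

A knowledge graph is multi-relational: every edge carries a predicate label.
The walk miner instead operates on a plain directed graph in which *only
vertices* are labeled.  Each triple ``(s, p, o)`` therefore becomes three
labeled vertices and two unlabeled edges::

    s  -->  p  -->  o

The predicate vertex is created fresh for every triple occurrence (its label
is shared, its identity is not).  Sharing a single vertex per predicate IRI
would merge unrelated triples: with triples ``(a, p, b)`` and ``(c, p, d)``
a shared ``p`` vertex would admit the spurious length-2 walk ``a -> p -> d``.

Entity vertices (subjects, objects, literals) are shared by string identity,
so the graph stitches triples together exactly where the KG does.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import networkx as nx
import pandas as pd
import rdflib
from rdflib.exceptions import ParserError
from rdflib.plugins.parsers.notation3 import BadSyntax
from rdflib.plugins.parsers.ntriples import W3CNTriplesParser

__all__ = [
    "Triple",
    "LabeledGraph",
    "Dataset",
    "TripleParseError",
    "EntityResolutionError",
    "load_triples",
    "load_exclusions",
    "convert_to_labeled_graph",
    "load_entity_labels",
    "entity_vertex_id",
    "load_edgelist_graph",
]


class Triple(NamedTuple):
    """A ``(subject, predicate, object)`` statement.

    Subjects and predicates are IRI (or blank-node) strings; the object may
    additionally be a literal, stored by its lexical form.
    """

    subject: str
    predicate: str
    object: str


class TripleParseError(ValueError):
    """Raised when an RDF file does not parse; message cites the location."""


class EntityResolutionError(KeyError):
    """Raised when labeled entities cannot be found in the graph."""

    def __init__(self, missing: Sequence[str]):
        self.missing = list(missing)
        super().__init__(
            "entities not present in graph: " + ", ".join(self.missing)
        )


@dataclass
class LabeledGraph:
    """Directed graph with a vertex-labeling function.

    Vertex ids are opaque hashables; ``label_of`` maps each vertex to its
    label string and several vertices may share a label.  Backed by a
    :class:`networkx.DiGraph` whose node attributes carry ``label`` and
    ``is_predicate``.
    """

    g: nx.DiGraph = field(default_factory=nx.DiGraph)

    # -- construction -----------------------------------------------------
    def add_vertex(self, vid, label: str, is_predicate: bool = False) -> None:
        self.g.add_node(vid, label=label, is_predicate=is_predicate)

    def add_edge(self, u, v) -> None:
        if u not in self.g or v not in self.g:
            raise KeyError(f"edge endpoint not in graph: {(u, v)}")
        self.g.add_edge(u, v)

    # -- queries ----------------------------------------------------------
    @property
    def vertices(self):
        return set(self.g.nodes)

    @property
    def edges(self):
        return set(self.g.edges)

    def label_of(self, vid) -> str:
        return self.g.nodes[vid]["label"]

    def is_predicate_node(self, vid) -> bool:
        return bool(self.g.nodes[vid].get("is_predicate", False))

    def successors(self, vid):
        return self.g.successors(vid)

    def __contains__(self, vid) -> bool:
        return vid in self.g

    def n_vertices(self) -> int:
        return self.g.number_of_nodes()

    def n_edges(self) -> int:
        return self.g.number_of_edges()


@dataclass
class Dataset:
    """Paired entity list ``V`` and label vector ``y``.

    Entities are vertex ids of the labeled graph; ``labels[i]`` is the class
    of ``entities[i]``.  Bootstrap resamples may repeat entities; entropy
    then counts each occurrence.
    """

    entities: list
    labels: list

    def __post_init__(self):
        if len(self.entities) != len(self.labels):
            raise ValueError("entities and labels must have equal length")
        if len(self.entities) == 0:
            raise ValueError("dataset must be non-empty")

    @property
    def classes(self) -> list:
        return sorted(set(self.labels))

    def __len__(self) -> int:
        return len(self.entities)

    def subset(self, indices: Iterable[int]) -> "Dataset":
        idx = list(indices)
        return Dataset([self.entities[i] for i in idx],
                       [self.labels[i] for i in idx])


class _CollectingGraph(rdflib.Graph):
    """rdflib Graph that records triples in the order the parser emits them."""

    def __init__(self, *args, **kwargs):
        super().__init__(*args, **kwargs)
        self.ordered: list[Triple] = []

    def add(self, triple):
        s, p, o = triple
        self.ordered.append(Triple(str(s), str(p), str(o)))
        return super().add(triple)


_FORMAT_ALIASES = {"ntriples": "nt", "nt": "nt", "turtle": "turtle", "ttl": "turtle"}


def load_triples(path, format: str = "ntriples") -> list[Triple]:
    """Parse an RDF file into a list of triples.

    Parameters
    ----------
    path : str or Path
        File in N-Triples or Turtle serialization.
    format : {"ntriples", "turtle"}
        Serialization name ("nt"/"ttl" accepted as aliases).

    Returns
    -------
    list of Triple, in file (parser-emission) order.  IRIs and blank-node
    ids are kept as strings; literals by their lexical form, verbatim.
    """
    fmt = _FORMAT_ALIASES.get(format)
    if fmt is None:
        raise ValueError(f"unknown RDF format {format!r}; use 'ntriples' or 'turtle'")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "nt":
        return _load_ntriples(path)
    g = _CollectingGraph()
    try:
        g.parse(source=str(path), format=fmt)
    except (ParserError, BadSyntax, ValueError) as exc:
        raise TripleParseError(f"failed to parse {path} as {format}: {exc}") from exc
    return g.ordered


class _ListSink:
    def __init__(self):
        self.triples: list[Triple] = []

    def triple(self, s, p, o):
        self.triples.append(Triple(str(s), str(p), str(o)))


def _load_ntriples(path: Path) -> list[Triple]:
    # NT is line-oriented: parsing per line preserves file order and lets
    # parse errors cite the offending line number
    sink = _ListSink()
    parser = W3CNTriplesParser(sink=sink)
    bnode_context: dict = {}
    for lineno, line in enumerate(
            path.read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        try:
            parser.parsestring(line, bnode_context=bnode_context)
        except ParserError as exc:
            raise TripleParseError(
                f"failed to parse {path} as ntriples at line {lineno}: {exc}"
            ) from exc
    return sink.triples


def load_exclusions(path) -> set[str]:
    """Read a label-leaking-predicate list: one IRI per line, '#' comments."""
    out: set[str] = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def entity_vertex_id(name: str):
    """Vertex id used for entity/literal vertices (shared by string identity)."""
    return ("ent", name)


def convert_to_labeled_graph(
    triples: Iterable[Triple],
    exclude_predicates: Iterable[str] = (),
) -> LabeledGraph:
    """Convert triples into the label-only directed graph.

    Triples whose predicate is excluded are dropped.  For every kept triple a
    fresh predicate vertex labeled with the predicate IRI is inserted between
    subject and object; subject/object vertices are shared across triples by
    string identity and labeled with their IRI/literal string.

    With ``T`` kept triples over ``E`` distinct entity strings the result has
    ``E + T`` vertices and ``2 T`` edges.
    """
    excluded = set(exclude_predicates)
    lg = LabeledGraph()
    pred_counter = 0
    for t in triples:
        if t.predicate in excluded:
            continue
        s_id, o_id = entity_vertex_id(t.subject), entity_vertex_id(t.object)
        if s_id not in lg:
            lg.add_vertex(s_id, t.subject)
        if o_id not in lg:
            lg.add_vertex(o_id, t.object)
        p_id = ("pred", pred_counter)
        pred_counter += 1
        lg.add_vertex(p_id, t.predicate, is_predicate=True)
        lg.add_edge(s_id, p_id)
        lg.add_edge(p_id, o_id)
    return lg


def load_entity_labels(path, graph: LabeledGraph) -> Dataset:
    """Read a TSV of (entity, label) rows and resolve entities in the graph.

    The file must have a header with columns ``entity`` and ``label``.
    Rows keep file order.  Duplicate rows with identical labels are collapsed
    with a warning; duplicates with conflicting labels are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"entity", "label"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"label file {path} must have columns 'entity' and 'label', "
            f"found {list(df.columns)}"
        )
    n_labels_per_entity = df.groupby("entity")["label"].nunique()
    conflicting = n_labels_per_entity[n_labels_per_entity > 1]
    if len(conflicting):
        raise ValueError(
            "conflicting labels for entities: " + ", ".join(conflicting.index)
        )
    if df["entity"].duplicated().any():
        warnings.warn("duplicate (entity, label) rows collapsed", stacklevel=2)
        df = df.drop_duplicates(subset="entity", keep="first")
    missing = [e for e in df["entity"] if entity_vertex_id(e) not in graph]
    if missing:
        raise EntityResolutionError(missing)
    return Dataset([entity_vertex_id(e) for e in df["entity"]], list(df["label"]))


def load_edgelist_graph(path) -> LabeledGraph:
    """Read a plain labeled directed graph from an edge-list TSV.

    The file has a header with columns ``src`` and ``dst``; each row is a
    directed edge between vertices named by those strings.  Every vertex is
    labeled with its own name — the layout used for the artificial example
    graphs, where walk mining runs with ``skip_odd=False``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"src", "dst"}.issubset(df.columns):
        raise ValueError(
            f"edge-list file {path} must have columns 'src' and 'dst', "
            f"found {list(df.columns)}"
        )
    lg = LabeledGraph()
    for name in pd.unique(df[["src", "dst"]].values.ravel()):
        lg.add_vertex(entity_vertex_id(name), name)
    for s, d in df[["src", "dst"]].itertuples(index=False):
        lg.add_edge(entity_vertex_id(s), entity_vertex_id(d))
    return lg
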