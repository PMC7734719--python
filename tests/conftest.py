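"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's frontier-expansion data
structure: walk containment is checked by exhaustively enumerating every
directed walk of the requested length, and information gain is recomputed
with scipy's entropy on explicitly constructed partitions.
"""

from collections import Counter

import pytest
from scipy.stats import entropy as scipy_entropy

from kgwalc import extract_neighborhoods, make_fig3_graph


# ---------------------------------------------------------------- oracles

def brute_walk_ends(graph, root, length):
    """Labels of endpoints of ALL directed walks of exactly `length` hops,
    found by explicit walk enumeration (exponential, tiny graphs only)."""
    ends = set()

    def rec(v, remaining):
        if remaining == 0:
            ends.add(graph.label_of(v))
            return
        for u in graph.successors(v):
            rec(u, remaining - 1)

    rec(root, length)
    return ends


def brute_contains(graph, root, end_label, depth):
    return end_label in brute_walk_ends(graph, root, depth)


def brute_entropy(labels):
    counts = list(Counter(labels).values())
    return float(scipy_entropy(counts, base=2))


def brute_info_gain(graph, data, end_label, depth):
    """IG of a (label, depth) walk computed from explicit walk enumeration."""
    found, not_found = [], []
    for v, y in zip(data.entities, data.labels):
        (found if brute_contains(graph, v, end_label, depth)
         else not_found).append(y)
    if not found or not not_found:
        return 0.0
    n = len(data)
    cond = (len(found) / n * brute_entropy(found)
            + len(not_found) / n * brute_entropy(not_found))
    return brute_entropy(data.labels) - cond


def brute_best_ig(graph, data, max_depth):
    """Maximum IG over every (label, depth<=max_depth) pair in the graph."""
    labels = {graph.label_of(v) for v in graph.vertices}
    return max(brute_info_gain(graph, data, lab, d)
               for lab in labels for d in range(1, max_depth + 1))


# ---------------------------------------------------------------- fixtures

@pytest.fixture(scope="session")
def fig3():
    graph, data = make_fig3_graph()
    nbhs = extract_neighborhoods(graph, data, depth=1)
    return graph, data, nbhs
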