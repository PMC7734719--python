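"""Entropy, information gain and top-n walk mining."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kgwalc import (Dataset, Walk, entropy, enumerate_candidates,
                    extract_neighborhood, extract_neighborhoods, info_gain,
                    make_random_graph, mine_walks, partition)
from kgwalc.kg_io import LabeledGraph, Triple, convert_to_labeled_graph
from kgwalc.walk_mining import walks_to_tsv
from tests.conftest import brute_best_ig, brute_entropy


class TestEntropy:
    @pytest.mark.parametrize("labels,expected", [
        (["a", "a", "a"], 0.0),                       # pure set
        (["a", "b"], 1.0),                            # uniform binary
        (["A"] * 8 + ["B"] * 2 + ["C"] * 2, 1.2516),  # 8/2/2 split
    ])
    def test_closed_forms(self, labels, expected):
        assert entropy(labels) == pytest.approx(expected, abs=1e-4)

    def test_empty_vector_is_an_error(self):
        with pytest.raises(ValueError):
            entropy([])

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.sampled_from("abcd"), min_size=1, max_size=40))
    def test_matches_scipy_and_is_bounded(self, labels):
        h = entropy(labels)
        assert h == pytest.approx(brute_entropy(labels), abs=1e-12)
        assert 0.0 <= h <= np.log2(len(set(labels))) + 1e-12


class TestPartitionAndGain:
    def test_degenerate_partitions(self, fig3):
        _, data, nbhs = fig3
        nowhere = Walk(depth=1, end_label="no-such-label")
        part = partition(data, nowhere, nbhs)
        assert part.found is None
        assert part.not_found.labels == data.labels
        assert info_gain(data, nowhere, nbhs) == 0.0

    def test_majority_hub_partition(self, fig3):
        # hub "1" is linked from all 8 majority entities and nobody else
        _, data, nbhs = fig3
        part = partition(data, Walk(depth=1, end_label="1"), nbhs)
        assert sorted(part.found.labels) == ["A"] * 8
        assert sorted(part.not_found.labels) == ["B", "B", "C", "C"]

    def test_gain_values_on_toy_graph(self, fig3):
        _, data, nbhs = fig3
        assert info_gain(data, Walk(1, "1"), nbhs) == pytest.approx(0.9183,
                                                                    abs=1e-4)
        assert info_gain(data, Walk(1, "6"), nbhs) == pytest.approx(0.6500,
                                                                    abs=1e-4)

    def test_missing_neighborhood_is_an_error(self, fig3):
        _, data, nbhs = fig3
        with pytest.raises(KeyError):
            partition(data, Walk(1, "1"), {})

    def test_gain_invariant_to_relabeling_and_order(self, fig3):
        _, data, nbhs = fig3
        w = Walk(1, "1")
        base = info_gain(data, w, nbhs)
        renamed = Dataset(data.entities,
                          [{"A": "z", "B": "q", "C": "m"}[y]
                           for y in data.labels])
        assert info_gain(renamed, w, nbhs) == pytest.approx(base)
        perm = list(reversed(range(len(data))))
        assert info_gain(data.subset(perm), w, nbhs) == pytest.approx(base)


class TestCandidates:
    def test_chain_candidates(self):
        g = LabeledGraph()
        for i, lab in enumerate("abc"):
            g.add_vertex(i, lab)
        g.add_edge(0, 1)
        g.add_edge(1, 2)
        nbhs = {0: extract_neighborhood(g, 0, 2)}
        assert enumerate_candidates(nbhs, 2) == {Walk(1, "b"), Walk(2, "c")}
        assert enumerate_candidates(nbhs, 2, skip_odd=True) == {Walk(2, "c")}

    def test_candidates_restricted_to_training_neighborhoods(self):
        # labels unreachable from any training entity never become candidates
        triples = [Triple("a", "p", "b"), Triple("x", "p", "y")]
        g = convert_to_labeled_graph(triples)
        data = Dataset([("ent", "a")], ["pos"])
        nbhs = extract_neighborhoods(g, data, 2)
        cands = enumerate_candidates(nbhs, 2)
        assert Walk(2, "y") not in cands
        assert Walk(2, "b") in cands


class TestMineWalks:
    def test_toy_graph_top1_is_majority_hub(self, fig3):
        _, data, nbhs = fig3
        top = mine_walks(data, nbhs, n=1, max_depth=1)
        assert top[0].walk == Walk(1, "1")  # lexicographic tie-break in 1..5
        assert top[0].ig == pytest.approx(0.9183, abs=1e-4)
        assert top[0].n_found == 8

    def test_toy_graph_majority_hubs_rank_before_minority_hubs(self, fig3):
        _, data, nbhs = fig3
        top = mine_walks(data, nbhs, n=7, max_depth=1)
        assert [s.walk.end_label for s in top] == list("1234567")
        assert top[4].ig > top[5].ig

    def test_single_class_dataset_all_zero_gain(self, fig3):
        _, data, nbhs = fig3
        mono = Dataset(data.entities, ["same"] * len(data))
        top = mine_walks(mono, nbhs, n=3, max_depth=1)
        assert len(top) == 3
        assert all(s.ig == 0.0 for s in top)

    def test_no_candidates_returns_empty(self):
        g = LabeledGraph()
        g.add_vertex(0, "a")
        g.add_vertex(1, "b")
        data = Dataset([0, 1], ["x", "y"])
        nbhs = extract_neighborhoods(g, data, 2)
        assert mine_walks(data, nbhs, n=1, max_depth=2) == []

    def test_candidate_fraction_requires_rng_and_samples(self, fig3):
        _, data, nbhs = fig3
        with pytest.raises(ValueError, match="rng"):
            mine_walks(data, nbhs, n=1, max_depth=1, candidate_fraction=0.5)
        rng = np.random.default_rng(0)
        top = mine_walks(data, nbhs, n=20, max_depth=1,
                         candidate_fraction=0.5, rng=rng)
        assert len(top) == 4  # ceil(0.5 * 7) candidates scored

    @settings(deadline=None, max_examples=30)
    @given(seed=st.integers(0, 10_000))
    def test_oracle_equivalence_brute_force_sweep(self, seed):
        """mine_walks(n=1) attains the max of a brute-force IG sweep over
        all (label, depth) pairs in the whole graph."""
        rng = np.random.default_rng(seed)
        g = make_random_graph(n_vertices=15, n_labels=4, edge_prob=0.15,
                              seed=seed)
        ents = sorted(g.vertices)[:8]
        data = Dataset(ents, [str(rng.integers(2)) for _ in ents])
        nbhs = {v: extract_neighborhood(g, v, 3) for v in ents}
        top = mine_walks(data, nbhs, n=1, max_depth=3)
        best_brute = brute_best_ig(g, data, 3)
        if top:
            assert top[0].ig == pytest.approx(best_brute, abs=1e-12)
        else:
            assert best_brute == pytest.approx(0.0)

    @settings(deadline=None, max_examples=20)
    @given(seed=st.integers(0, 10_000))
    def test_gain_bounded_by_prior_entropy(self, seed):
        rng = np.random.default_rng(seed)
        g = make_random_graph(15, 3, 0.2, seed=seed)
        ents = sorted(g.vertices)[:10]
        data = Dataset(ents, [str(rng.integers(3)) for _ in ents])
        nbhs = {v: extract_neighborhood(g, v, 3) for v in ents}
        prior = entropy(data.labels)
        for s in mine_walks(data, nbhs, n=100, max_depth=3):
            assert 0.0 <= s.ig <= prior + 1e-12


def test_walks_tsv_round_trip(tmp_path, fig3):
    import pandas as pd
    _, data, nbhs = fig3
    scored = mine_walks(data, nbhs, n=3, max_depth=1)
    out = tmp_path / "walks.tsv"
    walks_to_tsv(scored, out)
    df = pd.read_csv(out, sep="\t")
    assert list(df.columns) == ["end_label", "depth", "ig_bits", "n_found"]
    assert len(df) == 3 and df["end_label"].astype(str).tolist() == ["1", "2", "3"]
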