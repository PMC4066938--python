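"""Modularity, pair F-measure and NMI, each checked against an independent
route (hand enumeration, closed forms, sklearn / networkx oracles)."""

import itertools
import random
from math import comb

import networkx as nx
import pytest
from sklearn.metrics import normalized_mutual_info_score

from niblpa import Partition, f_measure, modularity, nmi
from niblpa.errors import ConsistencyError, UndefinedMetricError

from .conftest import random_graph, random_membership


def _partition_pairs(p: Partition) -> set:
    pairs = set()
    for c in p.communities:
        pairs.update(frozenset(x) for x in itertools.combinations(sorted(c), 2))
    return pairs


class TestModularity:
    def test_single_community_is_zero(self, toy_graph):
        p = Partition([set(toy_graph.nodes)])
        assert modularity(toy_graph, p) == pytest.approx(0.0)

    def test_two_triangles_with_bridge(self):
        G = nx.Graph(weighted=False)
        G.add_edges_from(
            [("a", "b"), ("b", "c"), ("a", "c"),
             ("d", "e"), ("e", "f"), ("d", "f"), ("c", "d")]
        )
        p = Partition([{"a", "b", "c"}, {"d", "e", "f"}])
        assert modularity(G, p) == pytest.approx(5 / 14)

    def test_toy_graph_true_split(self, toy_graph):
        p = Partition([{"v1", "v2", "v3"}, {"v4", "v5", "v6"}])
        assert modularity(toy_graph, p) == pytest.approx(0.25)

    def test_all_singletons_closed_form(self):
        rng = random.Random(31)
        for _ in range(20):
            G = random_graph(rng, 10, 0.4)
            G.remove_nodes_from([v for v in list(G) if G.degree[v] == 0])
            if G.number_of_edges() == 0:
                continue
            p = Partition([{v} for v in G])
            m = G.number_of_edges()
            expected = -sum(G.degree[v] ** 2 for v in G) / (2 * m) ** 2
            assert modularity(G, p) == pytest.approx(expected)

    def test_matches_networkx_on_random_partitions(self):
        rng = random.Random(8)
        for _ in range(30):
            G = random_graph(rng, 12, 0.4)
            if G.number_of_edges() == 0:
                continue
            p = Partition.from_membership(
                {v: rng.randrange(3) for v in G}
            )
            expected = nx.algorithms.community.modularity(
                G, [set(c) for c in p.communities]
            )
            assert modularity(G, p) == pytest.approx(expected, abs=1e-12)

    def test_edgeless_graph_undefined(self):
        G = nx.Graph()
        G.add_nodes_from("ab")
        with pytest.raises(UndefinedMetricError):
            modularity(G, Partition([{"a"}, {"b"}]))

    def test_partition_mismatch_raises(self, toy_graph):
        with pytest.raises(ConsistencyError):
            modularity(toy_graph, Partition([{"v1"}]))


class TestFMeasure:
    def test_identical_partitions_score_one(self):
        p = Partition([{"1", "2"}, {"3", "4", "5"}])
        assert f_measure(p, p) == 1.0

    def test_hand_enumerated_example(self):
        """truth {1,2},{3,4} vs pred {1,2,3},{4}: S = {12,13,23}, T = {12,34},
        overlap {12} -> precision 1/3, recall 1/2, F = 0.4."""
        truth = Partition([{"1", "2"}, {"3", "4"}])
        pred = Partition([{"1", "2", "3"}, {"4"}])
        assert f_measure(pred, truth) == pytest.approx(0.4)

    def test_all_singletons_pred_scores_zero(self):
        truth = Partition([{"1", "2"}, {"3"}])
        pred = Partition([{"1"}, {"2"}, {"3"}])
        assert f_measure(pred, truth) == 0.0

    def test_both_all_singletons_scores_one(self):
        p = Partition([{"1"}, {"2"}])
        assert f_measure(p, p) == 1.0

    def test_matches_pair_set_enumeration(self):
        rng = random.Random(5)
        for _ in range(30):
            n = rng.randint(2, 10)
            x = Partition.from_membership(random_membership(rng, n))
            y = Partition.from_membership(random_membership(rng, n))
            s, t = _partition_pairs(x), _partition_pairs(y)
            got = f_measure(x, y)
            if not s and not t:
                assert got == 1.0
            elif not s or not t:
                assert got == 0.0
            else:
                prec = len(s & t) / len(s)
                rec = len(s & t) / len(t)
                expected = (
                    0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)
                )
                assert got == pytest.approx(expected)


class TestNmi:
    def test_identical_partitions_score_one(self):
        p = Partition([{"1", "2"}, {"3", "4"}, {"5"}])
        assert nmi(p, p) == pytest.approx(1.0)

    def test_orthogonal_split_scores_zero(self):
        x = Partition([{"1", "2"}, {"3", "4"}])
        y = Partition([{"1", "3"}, {"2", "4"}])
        assert nmi(x, y) == pytest.approx(0.0)

    def test_both_trivial_is_one_single_trivial_is_zero(self):
        whole = Partition([{"1", "2", "3"}])
        split = Partition([{"1"}, {"2", "3"}])
        assert nmi(whole, whole) == 1.0
        assert nmi(whole, split) == pytest.approx(0.0)
        assert nmi(split, whole) == pytest.approx(0.0)

    def test_symmetry_and_relabel_invariance(self):
        rng = random.Random(13)
        for _ in range(20):
            n = rng.randint(2, 12)
            x = Partition.from_membership(random_membership(rng, n))
            y = Partition.from_membership(random_membership(rng, n))
            assert nmi(x, y) == pytest.approx(nmi(y, x))
            shuffled = Partition.from_membership(
                {v: 97 - c for v, c in x.membership.items()}
            )
            assert nmi(shuffled, y) == pytest.approx(nmi(x, y))

    def test_oracle_equivalence_with_sklearn(self):
        """Sum-normalized NMI equals sklearn's arithmetic-mean NMI to
        1e-12 on 200 random partition pairs."""
        rng = random.Random(77)
        for _ in range(200):
            n = rng.randint(2, 12)
            x = Partition.from_membership(random_membership(rng, n))
            y = Partition.from_membership(random_membership(rng, n))
            nodes = sorted(x.nodes)
            expected = normalized_mutual_info_score(
                [x.membership[v] for v in nodes],
                [y.membership[v] for v in nodes],
                average_method="arithmetic",
            )
            assert nmi(x, y) == pytest.approx(expected, abs=1e-12)

    def test_brute_force_on_exhaustive_small_partitions(self):
        """Against a from-scratch contingency computation on all partitions
        of a 4-node set (Bell(4) = 15 partitions, 225 pairs)."""
        from math import log

        nodes = ["a", "b", "c", "d"]

        def all_partitions(items):
            if not items:
                yield []
                return
            head, *rest = items
            for part in all_partitions(rest):
                for i in range(len(part)):
                    yield part[:i] + [part[i] | {head}] + part[i + 1:]
                yield part + [{head}]

        parts = [Partition(p) for p in all_partitions(nodes)]
        n = len(nodes)
        for x in parts:
            for y in parts:
                num = 0.0
                for cx in x.communities:
                    for cy in y.communities:
                        nij = len(cx & cy)
                        if nij:
                            num += nij * log(n * nij / (len(cx) * len(cy)))
                den = sum(len(c) * log(len(c) / n) for c in x.communities)
                den += sum(len(c) * log(len(c) / n) for c in y.communities)
                expected = 1.0 if den == 0 else min(1.0, max(0.0, -2 * num / den))
                assert nmi(x, y) == pytest.approx(expected, abs=1e-12)

    def test_node_set_mismatch_raises(self):
        with pytest.raises(ConsistencyError):
            nmi(Partition([{"1"}]), Partition([{"2"}]))


def test_all_metrics_invariant_under_relabeling(toy_graph):
    truth = Partition([{"v1", "v2", "v3"}, {"v4", "v5", "v6"}])
    relabeled = Partition.from_membership(
        {v: "blue" if truth.membership[v] else "red" for v in truth.membership}
    )
    pred = Partition([{"v1", "v2"}, {"v3", "v4", "v5", "v6"}])
    assert modularity(toy_graph, relabeled) == pytest.approx(
        modularity(toy_graph, truth)
    )
    assert f_measure(pred, relabeled) == pytest.approx(f_measure(pred, truth))
    assert nmi(pred, relabeled) == pytest.approx(nmi(pred, truth))
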