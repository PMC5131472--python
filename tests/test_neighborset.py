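import math

import networkx as nx
import pytest

from _oracles import oracle_predict_weight
from conftest import random_weighted_graph
from netweights import (
    NeighborSetPredictor,
    cross_probability,
    cross_ratio,
    predict_weight,
    predict_weights,
    within_estimate,
    within_probability,
    within_ratio,
)
from netweights.neighborset import CrossSetEvidence, WithinSetEvidence


def graph_of(weighted_edges):
    G = nx.Graph()
    for u, v, w in weighted_edges:
        G.add_edge(u, v, weight=w)
    return G


class TestWithinRatio:
    def test_no_internal_links_gives_smoothing_floor(self):
        G = graph_of([("alpha", "x", 0.2), ("alpha", "y", 0.3)])
        assert within_ratio(G, "alpha", ("x", "y")) == 1.0

    def test_fig1_hand_value(self, fig1_weighted):
        # only internal link of Γ(alpha) is (b, c): 0.6 / (0.4 * 0.8) = 1.875
        assert within_ratio(fig1_weighted, "alpha", ("a", "b")) == pytest.approx((1 + 1.875) / 2)

    def test_two_links_with_ratios_two_and_four(self):
        G = graph_of(
            [
                ("alpha", "i", 0.5), ("alpha", "j", 0.5), ("i", "j", 0.5),   # 0.5/0.25 = 2
                ("alpha", "u", 0.5), ("alpha", "v", 0.5), ("u", "v", 1.0),   # 1.0/0.25 = 4
            ]
        )
        assert within_ratio(G, "alpha", ("p", "q")) == pytest.approx(7 / 3)

    def test_excluded_pair_not_counted(self, fig1_weighted):
        # excluding (b, c) removes the only internal link of Γ(alpha)
        assert within_ratio(fig1_weighted, "alpha", ("b", "c")) == 1.0


class TestWithinEstimate:
    def test_fig1_hand_value(self, fig1_weighted):
        assert within_estimate(fig1_weighted, "alpha", "a", "b") == pytest.approx(0.5 * 0.4 * 1.4375)

    def test_pure_product_when_no_internal_links(self):
        G = graph_of([("alpha", "x", 0.2), ("alpha", "y", 0.3)])
        assert within_estimate(G, "alpha", "x", "y") == pytest.approx(0.06)

    def test_consistent_multiplicative_weights_give_plain_product(self):
        # one internal link whose ratio is exactly 1
        G = graph_of([("alpha", "i", 0.5), ("alpha", "j", 0.5), ("i", "j", 0.25),
                      ("alpha", "x", 0.2), ("alpha", "y", 0.3)])
        assert within_estimate(G, "alpha", "x", "y") == pytest.approx(0.2 * 0.3)

    def test_non_neighbor_rejected(self, fig1_weighted):
        with pytest.raises(ValueError):
            within_estimate(fig1_weighted, "alpha", "a", "e")

    def test_scale_law_in_unsmoothed_regime(self):
        """With no internal links (m = 0) the estimate scales as c^2."""
        G = graph_of([("alpha", "x", 0.2), ("alpha", "y", 0.3), ("alpha", "u", 0.9)])
        base = within_estimate(G, "alpha", "x", "y")
        for c in (0.5, 0.25, 0.1):
            H = graph_of([(u, v, c * d["weight"]) for u, v, d in G.edges(data=True)])
            assert within_estimate(H, "alpha", "x", "y") == pytest.approx(c**2 * base, rel=1e-12)


class TestWithinProbability:
    def test_fig1_density(self, fig1_weighted):
        assert within_probability(fig1_weighted, "alpha", ("a", "b")) == pytest.approx(1 / 6)

    def test_complete_neighborhood(self):
        G = graph_of([("alpha", "i", 1.0), ("alpha", "j", 1.0), ("i", "j", 1.0)])
        assert within_probability(G, "alpha", ("p", "q")) == 1.0

    def test_star_center_has_zero_density(self):
        G = graph_of([("hub", "a", 1.0), ("hub", "b", 1.0), ("hub", "c", 1.0)])
        assert within_probability(G, "hub", ("p", "q")) == 0.0

    def test_degree_below_two_gives_zero(self):
        G = graph_of([("alpha", "x", 1.0)])
        assert within_probability(G, "alpha", ("p", "q")) == 0.0

    def test_matches_local_clustering_coefficient(self):
        """With no exclusion inside Γ(α), the density is nx.clustering."""
        for seed in range(6):
            G = random_weighted_graph(seed)
            cc = nx.clustering(G)  # unweighted local clustering, independent reference
            for v in sorted(G.nodes()):
                assert within_probability(G, v, ("zz1", "zz2")) == pytest.approx(cc[v], abs=1e-12)


class TestCrossRatio:
    def test_no_cross_links_gives_smoothing_floor(self):
        G = graph_of([("alpha", "x", 0.5), ("beta", "y", 0.5)])
        assert cross_ratio(G, "alpha", "beta", ("p", "q")) == 1.0

    def test_fig1_hand_value(self, fig1_weighted):
        # only cross link is (d, e): 0.25 / (w_alpha_d * w_beta_e) = 0.25 / 0.25 = 1
        assert cross_ratio(fig1_weighted, "alpha", "beta", ("a", "f")) == pytest.approx(1.0)

    def test_two_links_with_ratios_one_and_three(self):
        G = graph_of(
            [
                ("alpha", "i", 0.5), ("beta", "j", 0.5), ("i", "j", 0.25),   # 0.25/0.25 = 1
                ("alpha", "u", 0.5), ("beta", "v", 0.5), ("u", "v", 0.75),   # 0.75/0.25 = 3
            ]
        )
        assert cross_ratio(G, "alpha", "beta", ("p", "q")) == pytest.approx(5 / 3)

    def test_symmetric_in_centers(self):
        for seed in range(5):
            G = random_weighted_graph(seed)
            nodes = sorted(G.nodes())
            for a, b in zip(nodes[:4], nodes[4:8]):
                assert cross_ratio(G, a, b, ("p", "q")) == cross_ratio(G, b, a, ("p", "q"))

    def test_identical_centers_rejected(self, fig1_weighted):
        with pytest.raises(ValueError):
            cross_ratio(fig1_weighted, "alpha", "alpha", ("p", "q"))


class TestCrossProbability:
    def test_fig1_density(self, fig1_weighted):
        # 1 cross link over 11 distinct cross pairs
        assert cross_probability(fig1_weighted, "alpha", "beta", ("a", "f")) == pytest.approx(1 / 11)

    def test_fully_interconnected_disjoint_neighborhoods(self):
        G = graph_of(
            [("alpha", "i", 1.0), ("alpha", "j", 1.0), ("beta", "u", 1.0),
             ("i", "u", 1.0), ("j", "u", 1.0)]
        )
        # Γ(alpha) = {i, j}, Γ(beta) = {u}; both cross pairs are links
        assert cross_probability(G, "alpha", "beta", ("p", "q")) == 1.0

    def test_no_cross_links(self):
        G = graph_of([("alpha", "i", 1.0), ("beta", "u", 1.0)])
        assert cross_probability(G, "alpha", "beta", ("p", "q")) == 0.0

    def test_empty_denominator(self):
        G = graph_of([("alpha", "x", 1.0), ("beta", "x", 1.0)])
        # Γ(alpha) = Γ(beta) = {x}: the only cross pair is the self-pair (x, x)
        assert cross_probability(G, "alpha", "beta", ("p", "q")) == 0.0

    def test_symmetric_in_centers(self, fig1_weighted):
        assert cross_probability(fig1_weighted, "alpha", "beta", ("a", "f")) == cross_probability(
            fig1_weighted, "beta", "alpha", ("a", "f")
        )


class TestPredictWeight:
    def test_isolated_pair_predicts_zero(self):
        G = graph_of([("a", "b", 1.0)])
        G.add_nodes_from(["x", "y"])
        assert predict_weight(G, "x", "y").predicted_weight == 0.0

    def test_symmetry(self):
        for seed in range(6):
            G = random_weighted_graph(seed)
            nodes = sorted(G.nodes())
            for x, y in zip(nodes[:5], nodes[5:10]):
                assert predict_weight(G, x, y).predicted_weight == predict_weight(G, y, x).predicted_weight

    def test_normalized_probabilities_sum_to_one(self, fig1_weighted):
        pred = predict_weight(fig1_weighted, "a", "b")
        assert sum(pred.normalized_probabilities) == pytest.approx(1.0)
        assert pred.predicted_weight == pytest.approx(
            sum(p * ev.estimate for p, ev in zip(pred.normalized_probabilities, pred.evidence))
        )

    def test_evidence_invariants(self, fig1_weighted):
        pred = predict_weight(fig1_weighted, "a", "f")
        assert pred.evidence, "a and f have neighbors on both sides"
        for ev in pred.evidence:
            assert 0.0 <= ev.probability <= 1.0
            assert ev.estimate >= 0.0
            if isinstance(ev, WithinSetEvidence):
                assert ev.center in set(fig1_weighted["a"]) & set(fig1_weighted["f"])
            else:
                assert isinstance(ev, CrossSetEvidence)
                a, b = ev.centers
                assert a != b

    def test_existing_edge_excluded_from_evidence(self):
        """Predicting a known link's weight equals predicting it after removal."""
        for seed in range(6):
            G = random_weighted_graph(seed)
            edges = sorted(G.edges())
            if not edges:
                continue
            x, y = edges[len(edges) // 2]
            H = G.copy()
            H.remove_edge(x, y)
            assert predict_weight(G, x, y).predicted_weight == pytest.approx(
                predict_weight(H, x, y).predicted_weight, rel=1e-12, abs=1e-15
            )

    def test_unknown_node_rejected(self, fig1_weighted):
        with pytest.raises(KeyError):
            predict_weight(fig1_weighted, "a", "nope")

    def test_matches_brute_force_oracle(self):
        for seed in range(25):
            G = random_weighted_graph(seed)
            nodes = sorted(G.nodes())
            for x, y in zip(nodes[::2], nodes[1::2]):
                expected = oracle_predict_weight(G, x, y)
                got = predict_weight(G, x, y).predicted_weight
                assert got == pytest.approx(expected, rel=1e-12, abs=1e-15)


class TestPredictWeights:
    def test_empty_batch(self, fig1_weighted):
        assert predict_weights(fig1_weighted, []) == []

    def test_batch_matches_single_calls(self):
        G = random_weighted_graph(11, n=20, p=0.3)
        nodes = sorted(G.nodes())
        pairs = [(x, y) for x in nodes[:10] for y in nodes[10:15] if x != y][:50]
        batch = predict_weights(G, pairs)
        singles = [predict_weight(G, x, y).predicted_weight for x, y in pairs]
        assert batch == singles

    def test_duplicate_pairs_give_duplicate_outputs(self, fig1_weighted):
        out = predict_weights(fig1_weighted, [("a", "b"), ("a", "b")])
        assert out[0] == out[1]

    def test_caching_does_not_change_results(self):
        G = random_weighted_graph(5)
        nodes = sorted(G.nodes())
        pairs = [(x, y) for x, y in zip(nodes[::2], nodes[1::2])]
        warm = NeighborSetPredictor(G)
        warm.predict_many(pairs)  # populate caches
        again = warm.predict_many(pairs)
        cold = [NeighborSetPredictor(G).predict(x, y).predicted_weight for x, y in pairs]
        assert again == cold
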