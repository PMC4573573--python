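import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from corrpath.correlation import CorrelationGraph
from corrpath.exceptions import DataValidationError
from corrpath.tsp import (MostCorrelatedCycle, build_model, canonical_cycle,
                          enumerate_oracle, sci_notation, solve_exact,
                          tour_space_size, tour_weight)

from conftest import random_graph


def graph_from_edges(ids, edges):
    n = len(ids)
    w = np.zeros((n, n))
    pos = {g: i for i, g in enumerate(ids)}
    for a, b, v in edges:
        w[pos[a], pos[b]] = w[pos[b], pos[a]] = v
    return CorrelationGraph(list(ids), w)


FOUR_RING = graph_from_edges(
    ["A", "B", "C", "D"],
    [("A", "B", 0.9), ("B", "C", 0.9), ("C", "D", 0.9), ("D", "A", 0.9),
     ("A", "C", 0.1), ("B", "D", 0.1)])


class TestBuildModel:
    def test_cost_map_and_arcs(self):
        model = build_model(FOUR_RING)
        assert model.cost[0, 1] == pytest.approx(0.1)   # weight 0.9
        assert model.cost[0, 2] == pytest.approx(0.9)   # weight 0.1
        assert len(model.arcs) == 4 * 3

    def test_supply_vector(self):
        model = build_model(FOUR_RING)
        np.testing.assert_array_equal(model.supply, [3, -1, -1, -1])
        assert model.supply.sum() == 0

    def test_too_small(self):
        with pytest.raises(DataValidationError):
            build_model(random_graph(np.random.default_rng(0), 2))


class TestCanonicalForm:
    def test_rotation_and_orientation(self):
        assert canonical_cycle(["C", "B", "A", "D"]) == ["A", "B", "C", "D"]
        assert canonical_cycle(["D", "C", "B", "A"]) == ["A", "B", "C", "D"]

    def test_weight_invariant_under_representation(self):
        order = ["B", "C", "D", "A"]
        assert tour_weight(FOUR_RING, order) == pytest.approx(
            tour_weight(FOUR_RING, canonical_cycle(order)))


class TestTourWeight:
    def test_uniform_weights(self):
        n = 5
        g = CorrelationGraph([f"n{i}" for i in range(n)],
                             0.4 * (1 - np.eye(n)))
        assert tour_weight(g, g.gene_ids) == pytest.approx(n * 0.4)

    def test_reversal_invariance(self):
        rng = np.random.default_rng(1)
        g = random_graph(rng, 6)
        order = list(rng.permutation(g.gene_ids))
        assert tour_weight(g, order) == pytest.approx(
            tour_weight(g, order[::-1]))

    def test_bad_permutation(self):
        with pytest.raises(DataValidationError):
            tour_weight(FOUR_RING, ["A", "A", "B", "C"])


class TestSolveExact:
    def test_three_nodes_unique_tour(self):
        g = random_graph(np.random.default_rng(2), 3)
        tour = solve_exact(build_model(g))
        w = g.weights
        assert tour.total_weight == pytest.approx(w[0, 1] + w[0, 2]
                                                  + w[1, 2])
        assert tour.optimal

    def test_four_ring_hand_optimum(self):
        tour = solve_exact(build_model(FOUR_RING))
        assert tour.node_ids == ["A", "B", "C", "D"]
        assert tour.total_weight == pytest.approx(3.6)

    def test_matches_oracle_small_random(self):
        for seed in range(6):
            rng = np.random.default_rng(300 + seed)
            g = random_graph(rng, int(rng.integers(4, 8)))
            a = solve_exact(build_model(g))
            b = enumerate_oracle(g)
            assert a.total_weight == pytest.approx(b.total_weight, abs=1e-9)

    def test_objective_consistency(self):
        g = random_graph(np.random.default_rng(7), 6)
        model = build_model(g)
        tour = solve_exact(model)
        cost = sum(model.cost[model.node_ids.index(a),
                              model.node_ids.index(b)]
                   for a, b in tour.edges())
        assert tour.total_weight + cost == pytest.approx(len(g.gene_ids))

    def test_node_order_invariance(self):
        rng = np.random.default_rng(8)
        g = random_graph(rng, 6)
        perm = list(rng.permutation(len(g.gene_ids)))
        g2 = CorrelationGraph([g.gene_ids[i] for i in perm],
                              g.weights[np.ix_(perm, perm)])
        assert solve_exact(build_model(g)).node_ids == \
            solve_exact(build_model(g2)).node_ids

    def test_source_independence(self):
        """The optimal value does not depend on which node holds the
        flow supply."""
        g = random_graph(np.random.default_rng(9), 6)
        model = build_model(g)
        weights = []
        for src in range(3):
            model.source = src
            weights.append(solve_exact(model).total_weight)
        assert max(weights) - min(weights) < 1e-9


class TestEnumerateOracle:
    def test_examines_all_permutations(self):
        g = random_graph(np.random.default_rng(10), 4)
        tour = enumerate_oracle(g)
        assert tour.stats["tours_examined"] == 6

    def test_combinatorial_guard(self):
        g = random_graph(np.random.default_rng(11), 11)
        with pytest.raises(DataValidationError, match="11"):
            enumerate_oracle(g)
        assert tour_space_size(28) == 304888344611713860501504000000

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_oracle_beats_random_tours(self, seed):
        rng = np.random.default_rng(seed)
        g = random_graph(rng, 7)
        best = enumerate_oracle(g).total_weight
        for _ in range(20):
            order = list(rng.permutation(g.gene_ids))
            assert tour_weight(g, order) <= best + 1e-12


class TestSciNotation:
    def test_truncate_vs_round(self):
        assert sci_notation(304888, 3, mode="truncate") == "3.04e+5"
        assert sci_notation(304888, 3, mode="round") == "3.05e+5"


class TestEstimatorFacade:
    def test_fit_on_precomputed_weights(self):
        est = MostCorrelatedCycle(precomputed=True,
                                  node_ids=FOUR_RING.gene_ids)
        est.fit(FOUR_RING.weights)
        assert est.predict() == ["A", "B", "C", "D"]
        assert est.tour_weight_ == pytest.approx(3.6)

    def test_fit_on_profiles(self):
        rng = np.random.default_rng(12)
        base = rng.normal(size=10)
        profiles = np.vstack([base + 0.05 * rng.normal(size=10)
                              for _ in range(5)])
        est = MostCorrelatedCycle().fit(profiles)
        assert len(est.tour_.node_ids) == 5
        assert est.tour_.optimal
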