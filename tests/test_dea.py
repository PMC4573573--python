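import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from corrpath.dea import (DEAConfig, DEAFrontierPeeler, bcc_score,
                          convex_frontier_2d, dea_efficient_set, dominates,
                          pareto_bruteforce, peel_frontiers)
from corrpath.exceptions import DataValidationError

from conftest import make_criteria, random_criteria


class TestDominates:
    def test_min_min_cases(self):
        d = ["minimize", "minimize"]
        assert dominates([1, 1], [2, 2], d)
        assert not dominates([2, 2], [1, 1], d)
        assert not dominates([1, 2], [2, 1], d)  # conflict, both ways
        assert not dominates([2, 1], [1, 2], d)
        assert not dominates([1, 1], [1, 1], d)  # equality fails Cond. 2

    def test_direction_aware(self):
        d = ["maximize", "minimize"]
        assert dominates([5, 1], [4, 2], d)
        assert not dominates([4, 1], [5, 2], d)

    def test_length_mismatch(self):
        with pytest.raises(DataValidationError):
            dominates([1], [1, 2], ["minimize", "minimize"])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_irreflexive_and_asymmetric(self, seed):
        rng = np.random.default_rng(seed)
        d = [str(rng.choice(["maximize", "minimize"])) for _ in range(3)]
        u, v = rng.uniform(0, 5, (2, 3))
        assert not dominates(u, u, d)
        assert not (dominates(u, v, d) and dominates(v, u, d))


class TestParetoBruteforce:
    def test_derived_min_min_instance(self):
        crit = make_criteria([[1, 5], [2, 3], [3, 4], [4, 2], [5, 1]],
                             ["minimize", "minimize"])
        assert pareto_bruteforce(crit) == {"g0", "g1", "g3", "g4"}

    def test_seven_point_conflict_layout(self):
        """Two candidates at the maximal-x / minimal-y extreme of a 7-point
        cloud are the only nondominated ones."""
        pts = [(1.0, 3.0), (2.0, 4.0), (6.0, 2.0),  # p3: best x
               (3.0, 5.0), (5.0, 1.0),              # p5: best y
               (2.5, 6.0), (3.5, 4.5)]
        crit = make_criteria(pts, ["maximize", "minimize"],
                             [f"p{i+1}" for i in range(7)])
        assert pareto_bruteforce(crit) == {"p3", "p5"}

    def test_all_identical_all_nondominated(self):
        crit = make_criteria(np.ones((4, 2)), ["minimize", "maximize"])
        assert pareto_bruteforce(crit) == {"g0", "g1", "g2", "g3"}


class TestBCCScore:
    def test_single_gene_scores_one(self):
        crit = make_criteria([[2.0, 3.0]], ["maximize", "minimize"],
                             ["solo"])
        for orientation in ("input", "output"):
            score, _ = bcc_score(crit, 0, orientation=orientation)
            assert score == pytest.approx(1.0, abs=1e-9)

    def test_min_min_with_dummy_output(self):
        crit = make_criteria([[1, 3], [2, 2], [3, 1], [3, 3]],
                             ["minimize", "minimize"])
        scores = dea_efficient_set(crit)
        assert list(scores.efficient) == [True, True, True, False]
        assert abs(scores.input_score[3] - 1.0) > 1e-6

    def test_column_scaling_preserves_classification(self):
        rng = np.random.default_rng(5)
        X = np.column_stack([rng.uniform(1, 10, 15), rng.uniform(1, 10, 15)])
        dirs = ["maximize", "minimize"]
        eff_a = dea_efficient_set(make_criteria(X, dirs)).efficient
        X2 = X.copy()
        X2[:, 1] *= 1000.0
        eff_b = dea_efficient_set(make_criteria(X2, dirs)).efficient
        np.testing.assert_array_equal(eff_a, eff_b)

    def test_interior_point_scores_off_one(self):
        # (1.5, 1.5) is strictly dominated by (1, 5): both scores must
        # land away from 1 (min first column, max second)
        crit = make_criteria([[1.0, 5.0], [5.0, 1.0], [2.0, 4.0],
                              [1.5, 1.5]],
                             ["minimize", "maximize"])
        scores = dea_efficient_set(crit)
        assert not scores.efficient[3]
        assert abs(scores.input_score[3] - 1.0) > 1e-6
        assert abs(scores.output_score[3] - 1.0) > 1e-6

    def test_epsilon_monotonicity(self):
        """Shrinking the non-Archimedean bound never shrinks the
        efficient set."""
        crit = random_criteria(np.random.default_rng(77))
        sets = []
        for eps in (1e-4, 1e-6, 1e-8):
            cfg = DEAConfig(epsilon=eps)
            sets.append(set(dea_efficient_set(crit, cfg).efficient_genes()))
        assert sets[0] <= sets[1] <= sets[2]


class TestHullOracle:
    def test_matches_efficient_set_on_seeded_instances(self):
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            n = int(rng.integers(5, 40))
            X = np.column_stack([rng.uniform(0.5, 10, n),
                                 rng.uniform(0.5, 10, n)])
            crit = make_criteria(X, ["maximize", "minimize"])
            eff = {i for i, e in
                   enumerate(dea_efficient_set(crit).efficient) if e}
            assert eff == set(convex_frontier_2d(X[:, 0], X[:, 1]))


class TestPeeling:
    def test_nested_antichains(self):
        """Inner min/min anti-chain forms frontier 1, the shifted outer
        copy frontier 2 (dummy maximized measure added automatically)."""
        inner = [(1, 4), (2, 3), (3, 2), (4, 1)]
        outer = [(2, 5), (3, 4), (4, 3), (5, 2)]
        crit = make_criteria(inner + outer, ["minimize", "minimize"])
        fa = peel_frontiers(crit, DEAConfig(num_frontiers=5))
        assert fa.frontier[:4] == [1, 1, 1, 1]
        assert fa.frontier[4:] == [2, 2, 2, 2]

    def test_single_frontier_equals_efficient_set(self):
        crit = random_criteria(np.random.default_rng(42))
        fa = peel_frontiers(crit, DEAConfig(num_frontiers=1))
        eff = set(dea_efficient_set(crit).efficient_genes())
        assert set(fa.genes_in_frontier(1)) == eff
        assert all(f in (1, None) for f in fa.frontier)

    def test_early_exhaustion(self):
        crit = make_criteria(np.random.default_rng(0).uniform(1, 5, (5, 2)),
                             ["maximize", "minimize"])
        fa = peel_frontiers(crit, DEAConfig(num_frontiers=10))
        assert all(f is not None and f <= 5 for f in fa.frontier)

    def test_duplicate_rows_efficient_together(self):
        crit = make_criteria([[1.0, 1.0], [1.0, 1.0], [2.0, 2.0]],
                             ["minimize", "minimize"])
        fa = peel_frontiers(crit)
        assert fa.frontier[0] == fa.frontier[1] == 1
        assert fa.frontier[2] == 2


class TestEstimatorFacade:
    def test_fit_predict_labels_match_functions(self):
        rng = np.random.default_rng(9)
        X = rng.uniform(1, 10, size=(12, 2))
        peeler = DEAFrontierPeeler(directions=["maximize", "minimize"],
                                   num_frontiers=3)
        labels = peeler.fit_predict(X)
        crit = make_criteria(X, ["maximize", "minimize"],
                             [str(i) for i in range(12)])
        fa = peel_frontiers(crit, DEAConfig(num_frontiers=3))
        expected = np.array([f if f is not None else -1
                             for f in fa.frontier])
        np.testing.assert_array_equal(labels, expected)
        assert peeler.support_.sum() == (labels > 0).sum()

    def test_get_set_params_round_trip(self):
        p = DEAFrontierPeeler(epsilon=1e-5)
        params = p.get_params()
        assert params["epsilon"] == 1e-5
        p.set_params(num_frontiers=4)
        assert p.num_frontiers == 4
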