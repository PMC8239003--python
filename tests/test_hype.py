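from collections import Counter
from fractions import Fraction

import numpy as np
import pytest

from ghype import DegreeSequence, HypeModel, MultiGraph, ValidationError
from ghype.oracle import enumerate_hype
from ghype.urns import mvhyper_sample_sequential

from conftest import enumerate_model_support, gof_pvalue


class TestLogPmf:
    def test_directed_two_cycle_is_one_sixth(self, toy_directed_model, two_cycle):
        assert toy_directed_model.pmf(two_cycle) == pytest.approx(1 / 6, abs=1e-14)

    def test_impossible_outcome_has_zero_probability(self, toy_directed_model):
        g = MultiGraph(counts=np.array([[2, 0], [0, 0]]), directed=True)
        assert toy_directed_model.log_pmf(g) == -np.inf

    def test_single_vertex_outcome_is_forced(self):
        for m in (1, 3, 5):
            model = HypeModel.from_degrees(DegreeSequence(k_out=[m], k_in=[m]))
            g = MultiGraph(counts=np.array([[m]]), directed=True)
            assert model.pmf(g) == pytest.approx(1.0, abs=1e-12)

    def test_undirected_unit_degree_outcomes(self, toy_undirected_model):
        edge = MultiGraph(counts=np.array([[0, 1], [1, 0]]), directed=False)
        loop0 = MultiGraph(counts=np.array([[2, 0], [0, 0]]), directed=False)
        loop1 = MultiGraph(counts=np.array([[0, 0], [0, 2]]), directed=False)
        assert toy_undirected_model.pmf(edge) == pytest.approx(1 / 2, abs=1e-14)
        assert toy_undirected_model.pmf(loop0) == pytest.approx(1 / 4, abs=1e-14)
        assert toy_undirected_model.pmf(loop1) == pytest.approx(1 / 4, abs=1e-14)

    def test_edge_count_mismatch_rejected(self, toy_directed_model):
        g = MultiGraph(counts=np.array([[0, 1], [0, 0]]), directed=True)
        with pytest.raises(ValidationError):
            toy_directed_model.log_pmf(g)

    @pytest.mark.parametrize(
        "deg",
        [
            DegreeSequence(k_out=[2, 1], k_in=[1, 2]),
            DegreeSequence(k_out=[1, 2, 1], k_in=[2, 1, 1]),
            DegreeSequence.undirected([2, 1, 1]),
            DegreeSequence.undirected([3, 2, 1]),
        ],
    )
    def test_normalizes_over_enumerated_support(self, deg):
        model = HypeModel.from_degrees(deg)
        total = sum(model.pmf(g) for g in enumerate_model_support(model))
        assert total == pytest.approx(1.0, abs=1e-12)


class TestMarginals:
    def test_toy_marginal_values(self, toy_directed_model):
        assert toy_directed_model.marginal_pmf(0, 1, 1) == pytest.approx(1 / 2, abs=1e-12)
        assert toy_directed_model.marginal_pmf(0, 1, 0) == pytest.approx(1 / 2, abs=1e-12)
        total = sum(toy_directed_model.marginal_pmf(0, 1, a) for a in range(3))
        assert total == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize(
        "deg", [DegreeSequence(k_out=[2, 1], k_in=[1, 2]), DegreeSequence.undirected([2, 2])]
    )
    def test_marginal_equals_joint_summed_over_support(self, deg):
        model = HypeModel.from_degrees(deg)
        support = enumerate_model_support(model)
        for i, j in ((0, 0), (0, 1), (1, 1)):
            for a in range(model.m + 1):
                if not model.directed and i == j:
                    joint = sum(model.pmf(g) for g in support if g.counts[i, j] == 2 * a)
                else:
                    joint = sum(model.pmf(g) for g in support if g.counts[i, j] == a)
                assert model.marginal_pmf(i, j, a) == pytest.approx(joint, abs=1e-12)


class TestExpectedAdjacency:
    def test_symmetric_toy(self, toy_directed_model):
        assert np.allclose(toy_directed_model.expected_adjacency(), 0.5)

    def test_hand_example_and_degree_recovery(self):
        model = HypeModel.from_degrees(DegreeSequence(k_out=[2, 1], k_in=[1, 2]))
        e = model.expected_adjacency()
        assert np.allclose(e, [[2 / 3, 4 / 3], [1 / 3, 2 / 3]])
        assert np.allclose(e.sum(axis=1), [2, 1])
        assert np.allclose(e.sum(axis=0), [1, 2])

    def test_undirected_expected_degree_counts_loops_twice(self, toy_undirected_model):
        e = toy_undirected_model.expected_adjacency()
        # edge w.p. 1/2 contributes 1; the vertex's own loop w.p. 1/4 contributes 2
        assert np.allclose(e.sum(axis=1), [1.0, 1.0])

    @pytest.mark.parametrize("directed", [True, False])
    def test_row_sums_match_degrees_exactly_rational(self, directed):
        rng = np.random.default_rng(42)
        for _ in range(10):
            n = int(rng.integers(2, 7))
            if directed:
                k_out = rng.integers(0, 6, size=n)
                k_in = rng.permutation(k_out)
                deg = DegreeSequence(k_out=k_out, k_in=k_in)
            else:
                k = rng.integers(0, 6, size=n)
                if k.sum() % 2:
                    k[0] += 1
                deg = DegreeSequence.undirected(k)
            if deg.m == 0:
                continue
            model = HypeModel.from_degrees(deg)
            exact = model.expected_adjacency_exact()
            row = [sum(exact[i, j] for j in range(n)) for i in range(n)]
            col = [sum(exact[i, j] for i in range(n)) for j in range(n)]
            assert row == [Fraction(int(v)) for v in deg.k_out]
            assert col == [Fraction(int(v)) for v in deg.k_in]


class TestDegreeDistribution:
    def test_toy_degree_pmf(self, toy_directed_model):
        values = [toy_directed_model.degree_pmf(0, k) for k in range(3)]
        assert values == pytest.approx([1 / 6, 4 / 6, 1 / 6], abs=1e-12)
        mean = sum(k * p for k, p in enumerate(values))
        assert mean == pytest.approx(1.0, abs=1e-12)

    def test_degree_variance_formula(self, toy_directed_model):
        assert toy_directed_model.degree_variance(0) == pytest.approx(1 / 3, abs=1e-14)

    def test_vertex_owning_all_stubs_has_zero_variance(self):
        model = HypeModel.from_degrees(DegreeSequence(k_out=[3, 0], k_in=[1, 2]))
        assert model.degree_variance(0) == 0.0

    def test_variance_always_below_degree(self):
        model = HypeModel.from_degrees(DegreeSequence(k_out=[4, 2, 1], k_in=[2, 2, 3]))
        for i, k in enumerate([4, 2, 1]):
            assert 0 < model.degree_variance(i) < k


class TestSampler:
    def test_every_sample_has_m_edges(self, toy_directed_model):
        for g in toy_directed_model.sample(200, seed=3):
            assert g.m == 2

    def test_seed_determinism(self, toy_directed_model):
        a = toy_directed_model.sample_counts(50, seed=11)
        b = toy_directed_model.sample_counts(50, seed=11)
        assert np.array_equal(a, b)

    def test_frequencies_match_enumerated_pmf(self, toy_directed_model):
        n_draws = 20000
        draws = toy_directed_model.sample_counts(n_draws, seed=5)
        observed = Counter(tuple(row) for row in draws)
        table = enumerate_hype(toy_directed_model.xi.urn_counts, 2)
        assert gof_pvalue(observed, table.as_dict(), n_draws) > 0.01

    def test_mean_sampled_degrees_match_inducing(self):
        deg = DegreeSequence(k_out=[3, 2, 1], k_in=[2, 2, 2])
        model = HypeModel.from_degrees(deg)
        draws = model.sample_counts(20000, seed=9).reshape(-1, 3, 3)
        mean_out = draws.sum(axis=2).mean(axis=0)
        se = draws.sum(axis=2).std(axis=0) / np.sqrt(draws.shape[0])
        assert np.all(np.abs(mean_out - deg.k_out) <= 3 * np.maximum(se, 1e-12))

    def test_sequential_sampler_is_order_invariant(self):
        counts = np.array([1, 2, 3])
        m = 3
        table = enumerate_hype(counts, m).as_dict()
        n_draws = 20000
        for order in ([0, 1, 2], [2, 0, 1]):
            rng = np.random.default_rng(17)
            observed = Counter(
                tuple(mvhyper_sample_sequential(counts, m, rng, order=order))
                for _ in range(n_draws)
            )
            assert gof_pvalue(observed, table, n_draws) > 0.01


def test_model_rejects_more_edges_than_urn():
    deg = DegreeSequence(k_out=[1, 1], k_in=[1, 1])
    from ghype.combinatorics import combinatorial_matrix

    with pytest.raises(ValidationError):
        HypeModel(xi=combinatorial_matrix(deg), m=5)
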