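from collections import Counter

import numpy as np
import pytest

from ghype import (
    DegreeSequence,
    GHypeModel,
    HypeModel,
    MultiGraph,
    PropensityMatrix,
    SaturationError,
    ValidationError,
    propensity_from_adjacency,
    propensity_from_graph,
)
from ghype.combinatorics import CombinatorialMatrix, combinatorial_matrix
from ghype.oracle import enumerate_wallenius
from ghype.urns import (
    wallenius_log_pmf,
    wallenius_marginal_pmf,
    wallenius_mean,
    wallenius_sample,
)

from conftest import enumerate_model_support, gof_pvalue


class TestWalleniusPmf:
    def test_single_draw_closed_form(self):
        # prefactor 1, S = 1, integral of (1 - z^2) dz = 2/3
        p = np.exp(wallenius_log_pmf([1, 1], [2.0, 1.0], [1, 0]))
        assert p == pytest.approx(2 / 3, abs=1e-12)

    def test_two_color_biased_urn(self):
        counts, omega = [2, 2], [2.0, 1.0]
        expected = {(2, 0): 1 / 3, (1, 1): 3 / 5, (0, 2): 1 / 15}
        total = 0.0
        for draw, want in expected.items():
            p = np.exp(wallenius_log_pmf(counts, omega, list(draw)))
            assert p == pytest.approx(want, abs=1e-10)
            total += p
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_zero_propensity_color_cannot_be_drawn(self):
        assert wallenius_log_pmf([2, 2], [1.0, 0.0], [1, 1]) == -np.inf

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_path_enumeration_on_random_urns(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 5))
        counts = rng.integers(1, 5, size=k)
        omega = rng.uniform(0.2, 3.0, size=k)
        m = int(rng.integers(1, min(6, counts.sum()) + 1))
        table = enumerate_wallenius(counts, omega, m)
        for outcome, want in zip(table.outcomes, table.probabilities):
            got = np.exp(wallenius_log_pmf(counts, omega, list(outcome)))
            assert got == pytest.approx(want, abs=1e-8)

    @pytest.mark.parametrize("lam", [1e-3, 1e3])
    def test_scale_invariance(self, lam):
        counts = [3, 2, 2]
        omega = np.array([1.3, 0.4, 2.1])
        draws = [2, 1, 1]
        base = wallenius_log_pmf(counts, omega, draws)
        scaled = wallenius_log_pmf(counts, lam * omega, draws)
        assert scaled == pytest.approx(base, abs=1e-10)


class TestUniformReduction:
    @pytest.mark.parametrize(
        "deg",
        [
            DegreeSequence(k_out=[1, 1], k_in=[1, 1]),
            DegreeSequence(k_out=[2, 1], k_in=[1, 2]),
            DegreeSequence.undirected([2, 1, 1]),
        ],
    )
    def test_constant_omega_reproduces_hype(self, deg):
        hype = HypeModel.from_degrees(deg)
        ghype = GHypeModel(xi=hype.xi, omega=PropensityMatrix.uniform(deg.n), m=deg.m)
        for g in enumerate_model_support(hype):
            assert ghype.pmf(g) == pytest.approx(hype.pmf(g), abs=1e-10)

    def test_constant_omega_marginals_match_hype(self):
        deg = DegreeSequence(k_out=[2, 1], k_in=[1, 2])
        hype = HypeModel.from_degrees(deg)
        ghype = GHypeModel(xi=hype.xi, omega=PropensityMatrix.uniform(2), m=3)
        for a in range(4):
            assert ghype.marginal_pmf(0, 1, a) == pytest.approx(
                hype.marginal_pmf(0, 1, a), abs=1e-10
            )

    def test_constant_omega_expectation_is_m_xi_over_M(self):
        deg = DegreeSequence(k_out=[2, 1], k_in=[1, 2])
        ghype = GHypeModel(
            xi=combinatorial_matrix(deg), omega=PropensityMatrix.uniform(2), m=3
        )
        assert np.allclose(
            ghype.expected_adjacency(), 3 * np.array([[2, 4], [1, 2]]) / 9.0, atol=1e-12
        )


class TestMarginals:
    def test_two_color_marginal_equals_joint(self):
        p = wallenius_marginal_pmf(2, 2.0, [2, 2], [2.0, 1.0], a=2, m=2)
        assert p == pytest.approx(1 / 3, abs=1e-10)

    def test_marginal_normalization(self):
        deg = DegreeSequence(k_out=[2, 2], k_in=[2, 2])
        omega = PropensityMatrix(omega=np.array([[2.0, 1.0], [0.5, 1.5]]))
        model = GHypeModel(xi=combinatorial_matrix(deg), omega=omega, m=4)
        total = sum(model.marginal_pmf(0, 1, a) for a in range(5))
        assert total == pytest.approx(1.0, abs=1e-8)


class TestExpectedAdjacency:
    def test_four_unit_colors_quadratic_solution(self):
        # t solves 1-t^2 + 3(1-t) = 2  =>  t = (-3 + sqrt(17)) / 2
        e = wallenius_mean([1, 1, 1, 1], [2.0, 1.0, 1.0, 1.0], 2)
        t = (-3 + np.sqrt(17)) / 2
        assert e[0] == pytest.approx(1 - t**2, abs=1e-12)
        assert np.allclose(e[1:], 1 - t, atol=1e-12)
        assert e.sum() == pytest.approx(2.0, abs=1e-12)

    def test_forced_full_urn(self):
        e = wallenius_mean([2, 3], [1.0, 2.0], 5)
        assert np.allclose(e, [2, 3])

    def test_infeasible_when_m_exceeds_positive_mass(self):
        from ghype import InfeasibleError

        with pytest.raises(InfeasibleError):
            wallenius_mean([2, 3], [1.0, 0.0], 3)


class TestPropensityEstimation:
    def test_constant_saturation_ratio_gives_uniform_omega(self):
        xi = CombinatorialMatrix(xi=np.full((2, 2), 4), directed=True)
        a = np.full((2, 2), 2)
        omega = propensity_from_adjacency(a, xi)
        assert np.allclose(omega.omega, 1.0)

    def test_hand_computed_omega(self):
        xi = CombinatorialMatrix(xi=np.full((2, 2), 4), directed=True)
        a = np.array([[2, 1], [1, 0]])
        omega = propensity_from_adjacency(a, xi)
        want = np.array([[1.0, 0.4150375], [0.4150375, 0.0]])
        assert np.allclose(omega.omega, want, atol=1e-7)
        # round trip: the centred ensemble's expectation is exactly A
        model = GHypeModel(xi=xi, omega=omega, m=4)
        assert np.allclose(model.expected_adjacency(), a, atol=1e-10)

    def test_saturated_dyad_raises_without_regularization(self):
        g = MultiGraph(counts=np.array([[0, 1], [1, 0]]), directed=True)
        with pytest.raises(SaturationError):
            propensity_from_graph(g)

    def test_regularization_shrinks_saturated_dyads(self):
        g = MultiGraph(counts=np.array([[0, 1], [1, 0]]), directed=True)
        omega = propensity_from_graph(g, regularize=1e-9)
        assert np.isfinite(omega.omega).all()
        assert omega.omega.max() == 1.0

    @pytest.mark.parametrize("directed", [True, False])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_round_trip_on_random_graphs(self, directed, seed):
        rng = np.random.default_rng(seed)
        while True:
            a = rng.poisson(1.5, size=(5, 5))
            if not directed:
                a = a + a.T  # symmetric with even diagonal
            g = MultiGraph(counts=a, directed=directed)
            if g.m == 0:
                continue
            try:
                omega = propensity_from_graph(g)
            except SaturationError:
                continue
            break
        model = GHypeModel.from_graph(g, omega)
        assert np.max(np.abs(model.expected_adjacency() - g.counts)) < 1e-6


class TestBiasedSampler:
    def test_every_sample_has_m_draws(self):
        draws = wallenius_sample([2, 2], [2.0, 1.0], 2, 500, np.random.default_rng(0))
        assert np.all(draws.sum(axis=1) == 2)

    def test_frequencies_match_enumerated_pmf(self):
        n_draws = 20000
        draws = wallenius_sample([2, 2], [2.0, 1.0], 2, n_draws, np.random.default_rng(1))
        observed = Counter(tuple(row) for row in draws)
        table = enumerate_wallenius([2, 2], [2.0, 1.0], 2)
        assert gof_pvalue(observed, table.as_dict(), n_draws) > 0.01

    def test_uniform_omega_matches_hype_law(self, toy_directed_model):
        n_draws = 20000
        counts = toy_directed_model.xi.urn_counts
        draws = wallenius_sample(counts, np.ones(4), 2, n_draws, np.random.default_rng(2))
        observed = Counter(tuple(row) for row in draws)
        from ghype.oracle import enumerate_hype

        assert gof_pvalue(observed, enumerate_hype(counts, 2).as_dict(), n_draws) > 0.01

    def test_model_sampler_seed_determinism(self):
        deg = DegreeSequence(k_out=[2, 2], k_in=[2, 2])
        omega = PropensityMatrix(omega=np.array([[2.0, 1.0], [0.5, 1.5]]))
        model = GHypeModel(xi=combinatorial_matrix(deg), omega=omega, m=4)
        assert np.array_equal(model.sample_counts(20, seed=7), model.sample_counts(20, seed=7))


def test_undirected_model_requires_symmetric_omega():
    deg = DegreeSequence.undirected([2, 2])
    with pytest.raises(ValidationError):
        GHypeModel(
            xi=combinatorial_matrix(deg),
            omega=PropensityMatrix(omega=np.array([[1.0, 0.5], [0.6, 1.0]])),
            m=2,
        )
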