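"""The hypergeometric configuration model (HypE).

A soft configuration model for multigraphs: ``m`` edges are drawn without
replacement from the urn of all stub pairings, so the adjacency count
vector follows the multivariate hypergeometric distribution.  The expected
degree sequence equals the inducing one exactly, the edge count is fixed
exactly, and the whole distribution is available in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import stats

from ._errors import ValidationError
from .combinatorics import CombinatorialMatrix, combinatorial_matrix
from .multigraph import DegreeSequence, MultiGraph, degree_sequences
from .urns import mvhyper_log_pmf, mvhyper_sample

__all__ = ["HypeModel"]


@dataclass(frozen=True)
class HypeModel:
    """Hypergeometric ensemble defined by a combinatorial matrix and edge count."""

    xi: CombinatorialMatrix
    m: int

    def __post_init__(self) -> None:
        if self.m < 0:
            raise ValidationError("edge count m must be non-negative")
        if self.m > self.xi.M:
            raise ValidationError(
                f"m={self.m} exceeds the urn total M={self.xi.M}; the model is degenerate"
            )

    @classmethod
    def from_graph(cls, g: MultiGraph) -> "HypeModel":
        """The model induced by a graph: its degrees and edge count."""
        return cls.from_degrees(degree_sequences(g))

    @classmethod
    def from_degrees(cls, deg: DegreeSequence) -> "HypeModel":
        return cls(xi=combinatorial_matrix(deg), m=deg.m)

    @property
    def directed(self) -> bool:
        return self.xi.directed

    @property
    def n(self) -> int:
        return self.xi.n

    # -- probability mass ------------------------------------------------

    def log_pmf(self, g: MultiGraph) -> float:
        """Log probability of observing the adjacency matrix of ``g``.

        Directed graphs use the ``C(Xi_ij, A_ij)`` product over all ordered
        pairs; undirected ones use ``C(2 Xi_ij, A_ij)`` off the diagonal and
        ``C(Xi_ll, A_ll / 2)`` on it, both against ``C(M, m)``.
        """
        draws = self.xi.graph_to_draws(g)
        if int(draws.sum()) != self.m:
            raise ValidationError(
                f"graph has {int(draws.sum())} edges but the model fixes m={self.m}"
            )
        return mvhyper_log_pmf(self.xi.urn_counts, draws)

    def pmf(self, g: MultiGraph) -> float:
        return float(np.exp(self.log_pmf(g)))

    def marginal_pmf(self, i: int, j: int, a: int) -> float:
        """Probability that the pair ``(i, j)`` carries exactly ``a`` edges.

        Univariate hypergeometric with the pair's urn count against the rest
        of the urn.  For an undirected diagonal, ``a`` is the self-loop
        multiplicity ``A_ll / 2`` (the number of loop balls drawn).
        """
        if a < 0 or a > self.m:
            raise ValidationError(f"edge count a={a} outside [0, m={self.m}]")
        good = self.xi.urn_count(i, j)
        return float(stats.hypergeom.pmf(a, self.xi.M, good, self.m))

    # -- moments ---------------------------------------------------------

    def expected_adjacency(self) -> np.ndarray:
        """Expected adjacency matrix, ``E[A_ij] = m Xi_ij / M`` (directed).

        Undirected entries are in adjacency units (doubled diagonal), so
        row and column sums reproduce the inducing degrees exactly.
        """
        xi = self.xi.xi.astype(float)
        if self.directed:
            return self.m * xi / self.xi.M
        e = 2.0 * self.m * xi / self.xi.M
        return e

    def expected_adjacency_exact(self) -> np.ndarray:
        """Rational-arithmetic expected adjacency (object array of Fractions)."""
        n = self.n
        M = self.xi.M
        out = np.empty((n, n), dtype=object)
        scale = 1 if self.directed else 2
        for i in range(n):
            for j in range(n):
                out[i, j] = Fraction(scale * self.m * int(self.xi.xi[i, j]), M)
        return out

    def degree_pmf(self, i: int, k: int) -> float:
        """Probability that vertex ``i`` realises out-degree ``k`` (directed).

        The favourable balls are all pairings of ``i``'s out-stubs,
        ``sum_j Xi_ij = m * k_out_i``, so the degree is hypergeometric.
        """
        if not self.directed:
            raise ValidationError("degree_pmf follows the directed out-degree law")
        good = int(self.xi.xi[i, :].sum())
        return float(stats.hypergeom.pmf(k, self.xi.M, good, self.m))

    def degree_variance(self, i: int) -> float:
        """Variance of vertex ``i``'s out-degree, ``k (m - k) / (m + 1)``."""
        if not self.directed:
            raise ValidationError("degree_variance follows the directed out-degree law")
        if self.m == 0:
            return 0.0
        k = int(self.xi.xi[i, :].sum()) // self.m  # m * k_out_i / m
        return k * (self.m - k) / (self.m + 1)

    # -- sampling --------------------------------------------------------

    def sample(self, n_samples: int, seed) -> list[MultiGraph]:
        """Draw ``n_samples`` exact realisations (every one has ``m`` edges)."""
        draws = self.sample_counts(n_samples, seed)
        return [self.xi.draws_to_graph(row) for row in draws]

    def sample_counts(self, n_samples: int, seed) -> np.ndarray:
        """Raw per-colour draw matrices, ``(n_samples, n_colors)``."""
        if n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        rng = np.random.default_rng(seed)
        return mvhyper_sample(self.xi.urn_counts, self.m, n_samples, rng)
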