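"""The generalized hypergeometric ensemble (gHypEG).

The hypergeometric configuration model draws edges uniformly from the urn
of stub pairings.  The generalized ensemble biases that draw with a matrix
of *edge propensities* Omega: the ratio ``Omega_ij / Omega_kl`` is the
odds-ratio of sampling a single edge at ``(i, j)`` rather than ``(k, l)``,
all else equal.  The adjacency counts then follow the multivariate
Wallenius non-central hypergeometric distribution.  With a constant Omega
the bias vanishes and the model reduces exactly to HypE.

Omega is defined only up to a positive scale; the canonical normalization
used here sets the largest entry to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._errors import SaturationError, ValidationError
from .combinatorics import CombinatorialMatrix, combinatorial_matrix
from .multigraph import MultiGraph, degree_sequences
from .urns import (
    wallenius_log_pmf,
    wallenius_marginal_pmf,
    wallenius_mean,
    wallenius_sample,
)

__all__ = ["PropensityMatrix", "GHypeModel", "propensity_from_graph", "propensity_from_adjacency"]


@dataclass(frozen=True)
class PropensityMatrix:
    """Relative edge propensities Omega (non-negative, defined up to scale)."""

    omega: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.omega, dtype=float).copy()
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValidationError(f"omega must be square, got shape {w.shape}")
        if not np.all(np.isfinite(w)) or np.any(w < 0):
            raise ValidationError("omega entries must be finite and non-negative")
        if not np.any(w > 0):
            raise ValidationError("omega must have at least one positive entry")
        w.setflags(write=False)
        object.__setattr__(self, "omega", w)

    @classmethod
    def uniform(cls, n: int) -> "PropensityMatrix":
        return cls(omega=np.ones((n, n)))

    @property
    def n(self) -> int:
        return self.omega.shape[0]

    def normalized(self) -> "PropensityMatrix":
        """Scale so the maximum entry is 1 (the canonical representative)."""
        return PropensityMatrix(omega=self.omega / self.omega.max())

    def is_symmetric(self) -> bool:
        return bool(np.allclose(self.omega, self.omega.T, rtol=0.0, atol=0.0))


@dataclass(frozen=True)
class GHypeModel:
    """gHypEG defined by a combinatorial matrix, a propensity matrix and m."""

    xi: CombinatorialMatrix
    omega: PropensityMatrix
    m: int

    def __post_init__(self) -> None:
        if self.omega.n != self.xi.n:
            raise ValidationError("omega and xi must have the same dimension")
        if not self.xi.directed and not self.omega.is_symmetric():
            raise ValidationError("undirected models require a symmetric omega")
        if self.m < 0:
            raise ValidationError("edge count m must be non-negative")
        effective = int(self.xi.urn_counts[self.color_omega > 0].sum())
        if self.m > effective:
            raise ValidationError(
                f"m={self.m} exceeds the {effective} stub pairings with positive propensity"
            )

    @classmethod
    def from_graph(cls, g: MultiGraph, omega: PropensityMatrix | np.ndarray) -> "GHypeModel":
        """The ensemble induced by a graph's degrees plus a given Omega."""
        if not isinstance(omega, PropensityMatrix):
            omega = PropensityMatrix(omega=omega)
        deg = degree_sequences(g)
        return cls(xi=combinatorial_matrix(deg), omega=omega, m=deg.m)

    @classmethod
    def fit_from_graph(cls, g: MultiGraph, regularize: float | None = None) -> "GHypeModel":
        """The ensemble centred on ``g``: Omega estimated so E[A] equals ``g``."""
        return cls.from_graph(g, propensity_from_graph(g, regularize=regularize))

    @property
    def directed(self) -> bool:
        return self.xi.directed

    @property
    def n(self) -> int:
        return self.xi.n

    @property
    def color_omega(self) -> np.ndarray:
        """Per-colour propensities aligned with ``xi.colors``."""
        w = self.omega.omega
        if self.directed:
            return w.ravel().copy()
        iu, ju = np.triu_indices(self.n)
        return w[iu, ju].copy()

    # -- probability mass ------------------------------------------------

    def log_pmf(self, g: MultiGraph) -> float:
        """Log probability of the adjacency matrix of ``g`` (Wallenius law)."""
        draws = self.xi.graph_to_draws(g)
        if int(draws.sum()) != self.m:
            raise ValidationError(
                f"graph has {int(draws.sum())} edges but the model fixes m={self.m}"
            )
        return wallenius_log_pmf(self.xi.urn_counts, self.color_omega, draws)

    def pmf(self, g: MultiGraph) -> float:
        return float(np.exp(self.log_pmf(g)))

    def marginal_pmf(self, i: int, j: int, a: int) -> float:
        """Probability that pair ``(i, j)`` carries exactly ``a`` edges.

        Collapses all other colours into one complement colour with the
        count-weighted mean propensity (the two-colour Wallenius form); for
        an undirected diagonal, ``a`` is the self-loop multiplicity.
        """
        if a < 0 or a > self.m:
            raise ValidationError(f"edge count a={a} outside [0, m={self.m}]")
        colors = self.xi.colors
        key = (i, j) if self.directed or i <= j else (j, i)
        focal = colors.index(key)
        counts = self.xi.urn_counts
        w = self.color_omega
        return wallenius_marginal_pmf(int(counts[focal]), float(w[focal]), counts, w, a, self.m)

    # -- moments ---------------------------------------------------------

    def expected_adjacency(self) -> np.ndarray:
        """Expected adjacency matrix in adjacency units.

        Per colour, ``E_k = c_k (1 - t^{w_k})`` with the scalar ``t``
        solving ``sum_k E_k = m``; undirected diagonals are doubled back
        into the adjacency convention.
        """
        e_colors = wallenius_mean(self.xi.urn_counts, self.color_omega, self.m)
        n = self.n
        out = np.zeros((n, n))
        if self.directed:
            out[:] = e_colors.reshape(n, n)
        else:
            iu, ju = np.triu_indices(n)
            vals = np.where(iu == ju, 2.0 * e_colors, e_colors)
            out[iu, ju] = vals
            out[ju, iu] = out[iu, ju]
        return out

    # -- sampling --------------------------------------------------------

    def sample(self, n_samples: int, seed) -> list[MultiGraph]:
        """Exact biased-urn draws realised as multigraphs."""
        rows = self.sample_counts(n_samples, seed)
        return [self.xi.draws_to_graph(row) for row in rows]

    def sample_counts(self, n_samples: int, seed) -> np.ndarray:
        if n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        rng = np.random.default_rng(seed)
        return wallenius_sample(self.xi.urn_counts, self.color_omega, self.m, n_samples, rng)


def propensity_from_adjacency(
    a: np.ndarray,
    xi: CombinatorialMatrix,
    regularize: float | None = None,
) -> PropensityMatrix:
    """Estimate Omega so that the gHypEG expectation equals ``a``.

    Inverts the expectation system: ``Omega_ij = log(1 - A_ij / Xi_ij) / c``
    for any negative constant ``c``; the canonical ``c`` is the one making
    the largest entry 1.  Pairs with ``A_ij = 0`` get ``Omega_ij = 0``.

    A saturated pair (``A_ij == Xi_ij``, in urn units) makes the logarithm
    diverge; by default this raises :class:`SaturationError`.  Passing
    ``regularize=eps`` shrinks such counts to ``(1 - eps) * Xi_ij`` first.
    """
    g = MultiGraph(counts=np.asarray(a), directed=xi.directed)
    draws = xi.graph_to_draws(g).astype(float)
    counts = xi.urn_counts.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(counts > 0, draws / np.where(counts > 0, counts, 1.0), 0.0)
    if np.any(draws[counts == 0] > 0):
        raise ValidationError("edges present at a pair with zero stub combinations")
    saturated = ratio >= 1.0
    if np.any(saturated):
        if regularize is None:
            pairs = [xi.colors[k] for k in np.nonzero(saturated)[0]]
            raise SaturationError(
                f"saturated pairs {pairs}: A_ij equals the available stub combinations; "
                "pass regularize=eps to shrink them"
            )
        ratio = np.where(saturated, 1.0 - float(regularize), ratio)
    raw = -np.log1p(-ratio)  # positive where edges are present
    if not np.any(raw > 0):
        raise ValidationError("cannot estimate propensities for an empty graph")
    w_colors = raw / raw.max()
    n = xi.n
    omega = np.zeros((n, n))
    if xi.directed:
        omega[:] = w_colors.reshape(n, n)
    else:
        iu, ju = np.triu_indices(n)
        omega[iu, ju] = w_colors
        omega[ju, iu] = omega[iu, ju]
    return PropensityMatrix(omega=omega)


def propensity_from_graph(g: MultiGraph, regularize: float | None = None) -> PropensityMatrix:
    """Estimate Omega from a graph against its own degree-induced urn."""
    xi = combinatorial_matrix(degree_sequences(g))
    return propensity_from_adjacency(g.counts, xi, regularize=regularize)
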