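"""Stub-pairing combinatorics: the matrix Xi and the induced urn.

For a degree sequence, ``Xi_ij = k_out_i * k_in_j`` counts the ways an
out-stub of vertex ``i`` can be wired to an in-stub of vertex ``j``.
Interpreting every stub pairing as a ball of colour ``(i, j)`` turns edge
sampling into an urn problem.  The per-colour ball counts are

* directed: ``Xi_ij`` for every ordered pair (``n^2`` colours);
* undirected: ``2 * Xi_ij`` for each unordered pair ``i < j`` (either stub
  of ``i`` may meet either stub of ``j``, in both roles) and ``Xi_ii`` on
  the diagonal (``n(n+1)/2`` colours).

In both cases the total ball count is ``M = sum_ij Xi_ij`` — ``m^2`` for a
directed graph with ``m`` edges, ``(2m)^2`` undirected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._errors import UndefinedOddsError, ValidationError
from .multigraph import DegreeSequence, MultiGraph

__all__ = ["CombinatorialMatrix", "combinatorial_matrix", "odds_ratio"]

_INT64_MAX = np.iinfo(np.int64).max


@dataclass(frozen=True)
class CombinatorialMatrix:
    """The matrix Xi of stub-pairing counts plus its urn representation.

    Attributes
    ----------
    xi
        ``(n, n)`` integer matrix, ``Xi_ij = k_out_i * k_in_j`` (directed)
        or ``k_i * k_j`` (undirected).
    directed
        Directedness of the underlying model.
    """

    xi: np.ndarray
    directed: bool

    def __post_init__(self) -> None:
        xi = np.asarray(self.xi)
        if xi.ndim != 2 or xi.shape[0] != xi.shape[1]:
            raise ValidationError(f"xi must be square, got shape {xi.shape}")
        if np.any(xi < 0):
            raise ValidationError("xi entries must be non-negative")
        # Python ints avoid silent overflow of M = m^2-scale totals.
        total = int(sum(int(v) for v in xi.ravel()))
        if total > _INT64_MAX:
            raise ValidationError("urn total M overflows 64-bit integers")
        xi = xi.astype(np.int64, copy=True)
        xi.setflags(write=False)
        object.__setattr__(self, "xi", xi)

    @property
    def n(self) -> int:
        return self.xi.shape[0]

    @property
    def M(self) -> int:
        """Total ball count in the urn (= sum of all Xi entries)."""
        return int(self.xi.sum())

    @property
    def colors(self) -> list[tuple[int, int]]:
        """Vertex pair of each urn colour, in fixed row-major order.

        Directed: all ordered pairs.  Undirected: pairs with ``i <= j``.
        """
        n = self.n
        if self.directed:
            return [(i, j) for i in range(n) for j in range(n)]
        return [(i, j) for i in range(n) for j in range(i, n)]

    @property
    def urn_counts(self) -> np.ndarray:
        """Per-colour ball counts aligned with :attr:`colors`."""
        n = self.n
        if self.directed:
            return self.xi.ravel().copy()
        iu, ju = np.triu_indices(n)
        counts = self.xi[iu, ju].copy()
        counts[iu != ju] *= 2
        return counts

    def urn_count(self, i: int, j: int) -> int:
        """Ball count of the colour for pair ``(i, j)``."""
        if self.directed:
            return int(self.xi[i, j])
        if i == j:
            return int(self.xi[i, i])
        return 2 * int(self.xi[i, j])

    def graph_to_draws(self, g: MultiGraph) -> np.ndarray:
        """Flatten an adjacency matrix into per-colour draw counts.

        Undirected diagonal entries (doubled convention) map to the number
        of loop balls drawn, ``A_ii / 2``.
        """
        if g.n != self.n or g.directed != self.directed:
            raise ValidationError("graph does not match the combinatorial matrix")
        a = g.counts
        if self.directed:
            return a.ravel().copy()
        iu, ju = np.triu_indices(self.n)
        draws = a[iu, ju].copy()
        draws[iu == ju] //= 2
        return draws

    def draws_to_graph(self, draws: np.ndarray) -> MultiGraph:
        """Inverse of :meth:`graph_to_draws`."""
        n = self.n
        a = np.zeros((n, n), dtype=np.int64)
        if self.directed:
            a[:] = np.asarray(draws).reshape(n, n)
        else:
            iu, ju = np.triu_indices(n)
            vals = np.asarray(draws, dtype=np.int64)
            a[iu, ju] = np.where(iu == ju, 2 * vals, vals)
            a[ju, iu] = a[iu, ju]
        return MultiGraph(counts=a, directed=self.directed)


def combinatorial_matrix(deg: DegreeSequence, directed: bool | None = None) -> CombinatorialMatrix:
    """Build Xi from a degree sequence (outer product of out- and in-degrees)."""
    if directed is None:
        directed = deg.directed
    elif directed != deg.directed:
        raise ValidationError("directed flag contradicts the degree sequence")
    xi = np.outer(deg.k_out.astype(object), deg.k_in.astype(object))
    return CombinatorialMatrix(xi=xi, directed=directed)


def odds_ratio(xi: CombinatorialMatrix, pair_a: tuple[int, int], pair_b: tuple[int, int]) -> float:
    """Relative odds of drawing one edge at ``pair_a`` vs ``pair_b``.

    Under the unbiased urn the odds of a single multi-edge are proportional
    to the ball counts, so this is ``urn_count(pair_a) / urn_count(pair_b)``.
    """
    denom = xi.urn_count(*pair_b)
    if denom == 0:
        raise UndefinedOddsError(f"pair {pair_b} has no stub combinations; odds undefined")
    return xi.urn_count(*pair_a) / denom
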