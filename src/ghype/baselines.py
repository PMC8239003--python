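"""Comparison models: multigraph Chung-Lu and the stub-matching CM.

The Chung-Lu multigraph model draws every entry of the adjacency matrix
independently, ``A_ij ~ Poisson(k_out_i k_in_j / m)``, so degrees and the
edge count are preserved only in expectation and each has Poisson variance
(Var[k_i] = k_i, Var[m] = m).  The standard configuration model (CM) is
realised by wiring stubs together uniformly at random, which preserves the
degree sequence exactly.  The CM sampler implements exactly that stub
matching process; over vertex-labeled multigraphs this realisation process
is the classical one but is not uniform over the graph space (a documented
caveat of stub matching, accepted here because the realisation process
itself is the model being compared).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from ._errors import ValidationError
from .multigraph import DegreeSequence, MultiGraph, degree_sequences

__all__ = ["ChungLuModel", "cm_stub_matching_sample"]


@dataclass(frozen=True)
class ChungLuModel:
    """Multigraph Chung-Lu model with independent Poisson edge counts."""

    rates: np.ndarray
    m: int
    directed: bool = True

    def __post_init__(self) -> None:
        lam = np.asarray(self.rates, dtype=float).copy()
        if lam.ndim != 2 or lam.shape[0] != lam.shape[1]:
            raise ValidationError("rates must be a square matrix")
        if np.any(lam < 0):
            raise ValidationError("Poisson rates must be non-negative")
        lam.setflags(write=False)
        object.__setattr__(self, "rates", lam)

    @classmethod
    def from_degrees(cls, deg: DegreeSequence) -> "ChungLuModel":
        """Rates ``lambda_ij = k_out_i k_in_j / m`` (directed).

        Undirected: ``k_i k_j / 2m`` per unordered pair and ``k_i^2 / 4m``
        per self-loop, matching the HypE expected adjacency; the total rate
        is ``m`` in both cases.
        """
        m = deg.m
        if m == 0:
            raise ValidationError("cannot build a Chung-Lu model from an empty graph")
        if deg.directed:
            lam = np.outer(deg.k_out, deg.k_in) / m
        else:
            k = deg.k.astype(float)
            lam = np.outer(k, k) / (2.0 * m)
            np.fill_diagonal(lam, k * k / (4.0 * m))
        return cls(rates=lam, m=m, directed=deg.directed)

    @classmethod
    def from_graph(cls, g: MultiGraph) -> "ChungLuModel":
        return cls.from_degrees(degree_sequences(g))

    @property
    def n(self) -> int:
        return self.rates.shape[0]

    def log_pmf(self, g: MultiGraph) -> float:
        """Sum of independent Poisson log masses over the free entries."""
        if g.n != self.n or g.directed != self.directed:
            raise ValidationError("graph does not match the model")
        if self.directed:
            lam = self.rates.ravel()
            a = g.counts.ravel().astype(float)
        else:
            iu, ju = np.triu_indices(self.n)
            lam = self.rates[iu, ju]
            a = g.counts[iu, ju].astype(float)
            a[iu == ju] /= 2.0  # loop multiplicity, not the doubled entry
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(a > 0, a * np.log(lam), 0.0)
        if np.any((lam == 0) & (a > 0)):
            return -np.inf
        return float(np.sum(terms - lam - gammaln(a + 1.0)))

    def sample(self, n_samples: int, seed) -> list[MultiGraph]:
        """Independent Poisson draws; the edge count varies across samples."""
        if n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        rng = np.random.default_rng(seed)
        out = []
        n = self.n
        if self.directed:
            for _ in range(n_samples):
                a = rng.poisson(self.rates)
                out.append(MultiGraph(counts=a, directed=True))
        else:
            iu, ju = np.triu_indices(n)
            lam = self.rates[iu, ju]
            for _ in range(n_samples):
                vals = rng.poisson(lam)
                a = np.zeros((n, n), dtype=np.int64)
                a[iu, ju] = np.where(iu == ju, 2 * vals, vals)
                a[ju, iu] = a[iu, ju]
                out.append(MultiGraph(counts=a, directed=False))
        return out


def cm_stub_matching_sample(
    deg: DegreeSequence, n_samples: int, seed
) -> list[MultiGraph]:
    """Standard configuration model samples via uniform stub matching.

    Directed: a uniformly random bijection of out-stubs onto in-stubs.
    Undirected: a uniformly random perfect matching of the ``2m`` stubs.
    Every sample reproduces the degree sequence exactly.
    """
    if n_samples < 1:
        raise ValidationError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    n = deg.n
    out: list[MultiGraph] = []
    if deg.directed:
        src = np.repeat(np.arange(n), deg.k_out)
        dst_pool = np.repeat(np.arange(n), deg.k_in)
        for _ in range(n_samples):
            dst = rng.permutation(dst_pool)
            a = np.zeros((n, n), dtype=np.int64)
            np.add.at(a, (src, dst), 1)
            out.append(MultiGraph(counts=a, directed=True))
    else:
        stubs = np.repeat(np.arange(n), deg.k)
        for _ in range(n_samples):
            order = rng.permutation(stubs)
            u, v = order[0::2], order[1::2]
            a = np.zeros((n, n), dtype=np.int64)
            np.add.at(a, (u, v), 1)
            np.add.at(a, (v, u), 1)
            out.append(MultiGraph(counts=a, directed=False))
    return out
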