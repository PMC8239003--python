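"""Synthetic heavy-tailed multigraph fixtures.

Emulates the shape of real collaboration networks (a few hundred vertices,
heavy-tailed degrees, around a thousand multi-edges): degrees are drawn
from a discrete power law ``P(k) ~ k^-alpha`` for ``k >= k_min``, parity is
repaired, and the graph is realised by uniform stub matching, which keeps
the drawn degree sequence exactly.
"""

from __future__ import annotations

import numpy as np

from ._errors import ParameterError
from .baselines import cm_stub_matching_sample
from .multigraph import DegreeSequence, MultiGraph

__all__ = ["synth_degree_sequence", "synth_multigraph"]


def _power_law_degrees(
    n: int, alpha: float, k_min: int, rng: np.random.Generator
) -> np.ndarray:
    # inverse-CDF sampling on the truncated support [k_min, k_min + 10n]
    k_max = k_min + 10 * n
    support = np.arange(k_min, k_max + 1)
    weights = support.astype(float) ** (-alpha)
    probs = weights / weights.sum()
    return rng.choice(support, size=n, p=probs)


def synth_degree_sequence(
    n: int,
    alpha: float = 2.2,
    k_min: int = 1,
    *,
    directed: bool = False,
    seed=None,
) -> DegreeSequence:
    """Power-law degree sequence with parity repaired.

    Undirected: if the degree total is odd, one uniformly chosen vertex
    gains a stub.  Directed: out- and in-degrees are drawn independently
    and the smaller total is topped up by unit increments of uniformly
    chosen vertices until the totals match.
    """
    if n < 2:
        raise ParameterError("need at least 2 vertices")
    if alpha <= 1:
        raise ParameterError("power-law exponent must exceed 1")
    if k_min < 1:
        raise ParameterError("k_min must be >= 1")
    rng = np.random.default_rng(seed)
    if directed:
        k_out = _power_law_degrees(n, alpha, k_min, rng).astype(np.int64)
        k_in = _power_law_degrees(n, alpha, k_min, rng).astype(np.int64)
        while k_out.sum() != k_in.sum():
            if k_out.sum() < k_in.sum():
                k_out[rng.integers(n)] += 1
            else:
                k_in[rng.integers(n)] += 1
        return DegreeSequence(k_out=k_out, k_in=k_in, directed=True)
    k = _power_law_degrees(n, alpha, k_min, rng).astype(np.int64)
    if k.sum() % 2 == 1:
        k[rng.integers(n)] += 1
    return DegreeSequence.undirected(k)


def synth_multigraph(
    n: int,
    alpha: float = 2.2,
    k_min: int = 1,
    m_target: int | None = None,
    *,
    directed: bool = False,
    seed=None,
    max_tries: int = 200,
) -> MultiGraph:
    """A random heavy-tailed multigraph, deterministic per seed.

    When ``m_target`` is given, degree sequences are redrawn (up to
    ``max_tries`` times) and the first one whose edge count lands within 5%
    of the target is kept (falling back to the closest draw).  The graph is
    then realised by one uniform stub matching, so its degree sequence is
    exactly the drawn one.
    """
    rng = np.random.default_rng(seed)
    if m_target is None:
        deg = synth_degree_sequence(n, alpha, k_min, directed=directed, seed=rng)
    else:
        best: DegreeSequence | None = None
        best_gap = np.inf
        for _ in range(max_tries):
            cand = synth_degree_sequence(n, alpha, k_min, directed=directed, seed=rng)
            gap = abs(cand.m - m_target)
            if gap < best_gap:
                best, best_gap = cand, gap
            if gap <= 0.05 * m_target:
                break
        deg = best
    return cm_stub_matching_sample(deg, 1, rng)[0]
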