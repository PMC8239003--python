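"""Brute-force ground truth for the urn distributions.

Intended for verification at toy scale: exhaustive enumeration of the
multivariate hypergeometric support with exact rational probabilities, and
an exact dynamic program over ordered draw paths for the biased (Wallenius)
urn.  Both tables exhaust the support and sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb

import numpy as np

from ._errors import ParameterError, ValidationError

__all__ = ["OutcomeTable", "enumerate_hype", "enumerate_wallenius"]


@dataclass(frozen=True)
class OutcomeTable:
    """Exhaustive (outcome, probability) table over an urn's support."""

    outcomes: tuple[tuple[int, ...], ...]
    probabilities: tuple  # Fractions (hypergeometric) or floats (Wallenius)

    def as_dict(self) -> dict[tuple[int, ...], object]:
        return dict(zip(self.outcomes, self.probabilities))

    def total(self):
        return sum(self.probabilities)


def _support(counts: tuple[int, ...], m: int, cap: int):
    """All per-colour draw vectors summing to m, bounded by counts."""
    out: list[tuple[int, ...]] = []

    def rec(idx: int, left: int, prefix: tuple[int, ...]):
        if idx == len(counts) - 1:
            if left <= counts[idx]:
                out.append(prefix + (left,))
                if len(out) > cap:
                    raise ParameterError(f"support exceeds the enumeration cap ({cap})")
            return
        tail = sum(counts[idx + 1:])
        lo = max(0, left - tail)
        for a in range(lo, min(counts[idx], left) + 1):
            rec(idx + 1, left - a, prefix + (a,))

    rec(0, m, ())
    return out


def enumerate_hype(urn_counts, m: int, cap: int = 10**6) -> OutcomeTable:
    """Exact multivariate hypergeometric PMF over the full support.

    Probabilities are exact rationals (products of binomial coefficients
    over ``C(M, m)``), so the table sums to 1 *exactly*.
    """
    counts = tuple(int(c) for c in urn_counts)
    if any(c < 0 for c in counts):
        raise ValidationError("urn counts must be non-negative")
    M = sum(counts)
    if m > M:
        raise ValidationError(f"cannot draw {m} balls from an urn of {M}")
    outcomes = _support(counts, m, cap)
    denom = comb(M, m)
    probs = tuple(
        Fraction(int(np.prod([comb(c, a) for c, a in zip(counts, out)], dtype=object)), denom)
        for out in outcomes
    )
    return OutcomeTable(outcomes=tuple(outcomes), probabilities=probs)


def enumerate_wallenius(urn_counts, omega, m: int, cap: int = 10**7) -> OutcomeTable:
    """Exact Wallenius PMF by summing ordered draw paths.

    At every step a ball is drawn with probability proportional to
    ``omega_k * remaining_k``; the dynamic program accumulates the
    probability of each (unordered) draw-count state level by level, which
    sums the path probabilities exactly (up to float round-off).
    """
    counts = tuple(int(c) for c in urn_counts)
    w = tuple(float(x) for x in omega)
    if len(w) != len(counts):
        raise ValidationError("omega must match the urn shape")
    if any(x < 0 for x in w):
        raise ValidationError("propensities must be non-negative")
    if m > sum(c for c, x in zip(counts, w) if x > 0):
        raise ValidationError("not enough balls with positive propensity")
    n_states = 1
    for c in counts:
        n_states *= c + 1
    if n_states * (m + 1) > cap:
        raise ParameterError(f"state space exceeds the enumeration cap ({cap})")

    level: dict[tuple[int, ...], float] = {tuple(0 for _ in counts): 1.0}
    for _ in range(m):
        nxt: dict[tuple[int, ...], float] = {}
        for state, prob in level.items():
            weights = [x * (c - a) for x, c, a in zip(w, counts, state)]
            total = sum(weights)
            for k, wk in enumerate(weights):
                if wk <= 0:
                    continue
                child = state[:k] + (state[k] + 1,) + state[k + 1:]
                nxt[child] = nxt.get(child, 0.0) + prob * wk / total
        level = nxt
    outcomes = tuple(sorted(level))
    return OutcomeTable(outcomes=outcomes, probabilities=tuple(level[o] for o in outcomes))
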