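"""Urn-level primitives shared by the ensemble models.

An urn is a vector of per-colour ball counts ``c`` from which ``m`` balls
are drawn without replacement.  Unbiased drawing yields the multivariate
hypergeometric distribution; drawing biased by per-colour weights (each
ball's probability proportional to weight x remaining count) yields the
multivariate Wallenius non-central hypergeometric distribution

    Pr(a) = [prod_k C(c_k, a_k)] * Int_0^1 prod_k (1 - z^(w_k / S))^(a_k) dz,
    S = sum_k w_k (c_k - a_k).

All probability mass is computed in log space via log-gamma.  The Wallenius
integral is evaluated after the substitution ``z = exp(-v)``, which turns
the monotone integrand on (0, 1) into a bell-shaped one on (0, inf); the
peak is located by bracketed root-finding on the log-derivative and the
integral is split there for adaptive quadrature (relative tolerance 1e-12).
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.special import gammaln

from ._errors import InfeasibleError, ValidationError

__all__ = [
    "log_binom",
    "mvhyper_log_pmf",
    "mvhyper_sample",
    "mvhyper_sample_sequential",
    "wallenius_log_pmf",
    "wallenius_marginal_pmf",
    "wallenius_mean",
    "wallenius_sample",
]


def log_binom(n, k):
    """``log C(n, k)`` elementwise; ``-inf`` outside ``0 <= k <= n``."""
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    out = np.full(np.broadcast(n, k).shape, -np.inf)
    ok = (k >= 0) & (k <= n)
    nn, kk = np.broadcast_arrays(n, k)
    out[ok] = (
        gammaln(nn[ok] + 1.0) - gammaln(kk[ok] + 1.0) - gammaln(nn[ok] - kk[ok] + 1.0)
    )
    if out.ndim == 0:
        return float(out)
    return out


def _check_urn(counts, draws):
    counts = np.asarray(counts, dtype=np.int64)
    draws = np.asarray(draws, dtype=np.int64)
    if counts.shape != draws.shape:
        raise ValidationError("counts and draws must have the same shape")
    if np.any(draws < 0):
        raise ValidationError("draw counts must be non-negative")
    return counts, draws


def mvhyper_log_pmf(counts, draws) -> float:
    """Log PMF of the multivariate hypergeometric distribution.

    ``counts`` are per-colour ball counts, ``draws`` the drawn count vector;
    the number of draws is ``m = sum(draws)``.
    """
    counts, draws = _check_urn(counts, draws)
    m = int(draws.sum())
    M = int(counts.sum())
    if m > M:
        return -np.inf
    terms = log_binom(counts, draws)
    if np.any(np.isneginf(terms)):
        return -np.inf
    return float(terms.sum() - log_binom(M, m))


def mvhyper_sample(counts, m: int, n_samples: int, rng: np.random.Generator) -> np.ndarray:
    """Exact multivariate hypergeometric draws, ``(n_samples, n_colors)``."""
    counts = np.asarray(counts, dtype=np.int64)
    if m > counts.sum():
        raise InfeasibleError(f"cannot draw {m} balls from an urn of {counts.sum()}")
    return rng.multivariate_hypergeometric(counts, m, size=n_samples, method="marginals")


def mvhyper_sample_sequential(
    counts, m: int, rng: np.random.Generator, order=None
) -> np.ndarray:
    """One exact draw via sequential conditional univariate hypergeometrics.

    Colours are visited in ``order`` (default: index order); at each step the
    number of balls of the current colour among the remaining draws is a
    univariate hypergeometric variate.  The resulting law does not depend on
    the ordering — a fact the test suite checks — so ``order`` exists for
    exactly that verification.
    """
    counts = np.asarray(counts, dtype=np.int64)
    if order is None:
        order = np.arange(counts.size)
    draws = np.zeros_like(counts)
    remaining_m = int(m)
    remaining_M = int(counts.sum())
    if remaining_m > remaining_M:
        raise InfeasibleError(f"cannot draw {m} balls from an urn of {remaining_M}")
    for k in order:
        if remaining_m == 0:
            break
        good = int(counts[k])
        a = int(rng.hypergeometric(good, remaining_M - good, remaining_m))
        draws[k] = a
        remaining_m -= a
        remaining_M -= good
    return draws


def _log_integrand_terms(v: float, exponents: np.ndarray, mult: np.ndarray) -> float:
    # log prod (1 - e^{-e_k v})^{a_k} = sum a_k log(-expm1(-e_k v))
    x = exponents * v
    return float(np.sum(mult * np.log(-np.expm1(-x))))


def _dlog_integrand(v: float, exponents: np.ndarray, mult: np.ndarray) -> float:
    # derivative of [-v + sum a_k log(1 - e^{-e_k v})]
    with np.errstate(over="ignore"):
        denom = np.expm1(exponents * v)
    return float(-1.0 + np.sum(mult * exponents / denom))


def _wallenius_log_integral(exponents: np.ndarray, mult: np.ndarray) -> float:
    """``log Int_0^1 prod_k (1 - z^{e_k})^{a_k} dz`` for positive exponents."""
    if exponents.size == 0:
        return 0.0

    def g(v: float) -> float:
        return -v + _log_integrand_terms(v, exponents, mult)

    # The log-derivative decreases monotonically from +inf to -1: bracket
    # its unique root (the peak of the transformed integrand).
    lo, hi = 1.0, 1.0
    while _dlog_integrand(hi, exponents, mult) > 0:
        hi *= 2.0
    while _dlog_integrand(lo, exponents, mult) < 0:
        lo /= 2.0
        if lo < 1e-300:
            break
    v_star = brentq(_dlog_integrand, lo, hi, args=(exponents, mult), xtol=1e-14, rtol=1e-13)
    shift = g(v_star)

    def integrand(v: float) -> float:
        return np.exp(g(v) - shift)

    left, _ = quad(integrand, 0.0, v_star, epsabs=0.0, epsrel=1e-12, limit=200)
    right, _ = quad(integrand, v_star, np.inf, epsabs=0.0, epsrel=1e-12, limit=200)
    return shift + np.log(left + right)


def wallenius_log_pmf(counts, omega, draws) -> float:
    """Log PMF of the multivariate Wallenius non-central hypergeometric law.

    ``omega`` are the per-colour propensities (defined up to scale); colours
    with zero propensity can never be drawn.
    """
    counts, draws = _check_urn(counts, draws)
    omega = np.asarray(omega, dtype=float)
    if omega.shape != counts.shape:
        raise ValidationError("omega must match the urn shape")
    if np.any(omega < 0) or not np.all(np.isfinite(omega)):
        raise ValidationError("propensities must be finite and non-negative")
    prefactor = log_binom(counts, draws)
    if np.any(np.isneginf(prefactor)):
        return -np.inf
    if np.any((omega == 0) & (draws > 0)):
        return -np.inf
    s_omega = float(np.sum(omega * (counts - draws)))
    active = draws > 0
    if not np.any(active):
        return float(prefactor.sum())  # m = 0: the empty draw is certain
    if s_omega == 0.0:
        # no ball with positive weight remains: the outcome was forced
        return float(prefactor.sum())
    exponents = omega[active] / s_omega
    log_integral = _wallenius_log_integral(exponents, draws[active].astype(float))
    return float(prefactor.sum()) + log_integral


def wallenius_marginal_pmf(c_focal: int, w_focal: float, counts, omega, a: int, m: int) -> float:
    """Marginal probability of drawing ``a`` balls of one colour.

    The remaining colours are collapsed into a single complement colour of
    ``M - c_focal`` balls with the count-weighted mean propensity
    ``w_bar = sum_{k != focal} c_k w_k / (M - c_focal)``; the probability is
    the two-colour Wallenius PMF of ``(a, m - a)``.
    """
    counts = np.asarray(counts, dtype=np.int64)
    omega = np.asarray(omega, dtype=float)
    M = int(counts.sum())
    c_rest = M - c_focal
    if a < 0 or a > m:
        raise ValidationError(f"marginal count a={a} outside [0, m={m}]")
    rest_mass = float(np.sum(counts * omega)) - c_focal * w_focal
    if c_rest > 0:
        w_bar = rest_mass / c_rest
    else:
        w_bar = 0.0
    return float(
        np.exp(
            wallenius_log_pmf(
                np.array([c_focal, c_rest]),
                np.array([w_focal, w_bar]),
                np.array([a, m - a]),
            )
        )
    )


def wallenius_mean(counts, omega, m: int) -> np.ndarray:
    """Expected per-colour draw counts under the Wallenius law.

    Solves ``sum_k c_k (1 - t^{w_k}) = m`` for the single unknown
    ``t in (0, 1)`` (the expression is monotone in ``t``) and returns
    ``E_k = c_k (1 - t^{w_k})``.  Zero-propensity colours get expectation 0.
    """
    counts = np.asarray(counts, dtype=np.int64)
    omega = np.asarray(omega, dtype=float)
    if np.any(omega < 0):
        raise ValidationError("propensities must be non-negative")
    pos = omega > 0
    if not np.any(pos):
        raise ValidationError("at least one propensity must be positive")
    effective = int(counts[pos].sum())
    if m > effective:
        raise InfeasibleError(
            f"m={m} exceeds the {effective} balls with positive propensity"
        )
    expected = np.zeros(counts.shape, dtype=float)
    if m == 0:
        return expected
    if m == effective:
        expected[pos] = counts[pos]
        return expected
    w = omega / omega[pos].max()  # scale freedom: condition the root-solve

    def excess(t: float) -> float:
        with np.errstate(invalid="ignore"):
            powed = np.where(pos, t ** w, 1.0)
        return float(np.sum(counts * (1.0 - powed))) - m

    t = brentq(excess, 0.0, 1.0, xtol=4e-16, rtol=8.9e-16)
    expected[pos] = counts[pos] * (1.0 - t ** w[pos])
    return expected


def wallenius_sample(
    counts, omega, m: int, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """Exact biased-urn draws, ``(n_samples, n_colors)``.

    Ball-by-ball scheme: at each of the ``m`` steps a colour is drawn with
    probability proportional to ``omega_k * remaining_k``, then one ball of
    that colour is removed.  This is the defining process of the Wallenius
    distribution, so the draws follow the exact law.
    """
    counts = np.asarray(counts, dtype=np.int64)
    omega = np.asarray(omega, dtype=float)
    n_colors = counts.size
    remaining = np.tile(counts.astype(float), (n_samples, 1))
    draws = np.zeros((n_samples, n_colors), dtype=np.int64)
    rows = np.arange(n_samples)
    for _ in range(m):
        weights = remaining * omega
        totals = weights.sum(axis=1)
        if np.any(totals <= 0):
            raise InfeasibleError("urn exhausted before drawing m balls")
        u = rng.random(n_samples) * totals
        chosen = (np.cumsum(weights, axis=1) <= u[:, None]).sum(axis=1)
        chosen = np.minimum(chosen, n_colors - 1)  # guard FP edge at u == total
        remaining[rows, chosen] -= 1.0
        draws[rows, chosen] += 1
    return draws
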