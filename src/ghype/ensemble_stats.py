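"""Per-graph summary statistics and the ensemble comparison experiment.

For each realisation we record the edge count, the mean squared deviation
of its degree sequence from the reference one, the Freeman-style degree
centralization, and the degree assortativity.  The comparison experiment
samples the three null models induced by one reference graph (stub-matching
CM, hypergeometric HypE, Chung-Lu CL), collects those statistics, and runs
three contrasts: a one-sided Welch t-test on degree-MSE (HypE < CL), a
one-sided bootstrap test on the variance of centralization (HypE < CL),
and two-sided Kolmogorov-Smirnov tests on assortativity for every model
pair.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy import stats

from ._errors import ValidationError
from .baselines import ChungLuModel, cm_stub_matching_sample
from .hype import HypeModel
from .multigraph import DegreeSequence, MultiGraph, degree_sequences

__all__ = ["GraphStats", "EnsembleSummary", "graph_stats", "run_comparison"]

MODEL_KINDS = ("cm", "hype", "chung-lu")


@dataclass(frozen=True)
class GraphStats:
    """Summary statistics of one realisation against a reference sequence."""

    m: int
    degree_mse: float
    centralization: float  # nan when undefined (n < 3)
    assortativity: float  # nan when undefined (zero degree variance)


@dataclass
class EnsembleSummary:
    """Raw per-model statistic arrays plus the contrast table."""

    stats: dict[str, list[GraphStats]]
    contrasts: list[dict] = field(default_factory=list)
    dropped_assortativity: dict[str, int] = field(default_factory=dict)

    def arrays(self, model: str, name: str) -> np.ndarray:
        return np.array([getattr(s, name) for s in self.stats[model]], dtype=float)

    def to_dict(self) -> dict:
        return {
            "models": {
                model: {
                    name: [getattr(s, name) for s in rows]
                    for name in ("m", "degree_mse", "centralization", "assortativity")
                }
                for model, rows in self.stats.items()
            },
            "contrasts": self.contrasts,
            "dropped_assortativity": self.dropped_assortativity,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1, allow_nan=True)


def _degrees_vector(g: MultiGraph) -> np.ndarray:
    deg = degree_sequences(g)
    if g.directed:
        return np.concatenate([deg.k_out, deg.k_in])
    return deg.k_out


def _reference_vector(ref: DegreeSequence) -> np.ndarray:
    if ref.directed:
        return np.concatenate([ref.k_out, ref.k_in])
    return ref.k_out


def degree_mse(g: MultiGraph, reference: DegreeSequence) -> float:
    """Mean squared deviation of the degree sequence from the reference.

    Directed graphs average over the concatenated out- and in-sequences.
    """
    got = _degrees_vector(g)
    want = _reference_vector(reference)
    if got.shape != want.shape:
        raise ValidationError("reference degree sequence does not match the graph")
    return float(np.mean((got - want) ** 2.0))


def centralization(g: MultiGraph) -> float:
    """Freeman-style degree centralization, ``sum(k_max - k_i) / ((n-1)(n-2))``.

    Directed graphs use total degrees (in + out).  Undefined (nan) for
    ``n < 3``.  The simple-graph normalisation is kept for every model so
    values are comparable across ensembles.
    """
    n = g.n
    if n < 3:
        return float("nan")
    deg = degree_sequences(g)
    k = (deg.k_out + deg.k_in) if g.directed else deg.k_out
    return float((k.max() - k).sum() / ((n - 1) * (n - 2)))


def assortativity(g: MultiGraph) -> float:
    """Degree assortativity: Pearson correlation of endpoint degrees.

    Each multi-edge counts with its multiplicity.  Directed: out-degree of
    the source against in-degree of the target.  Undirected: both
    orientations of every edge enter the edge list (the standard
    symmetrisation).  Returns nan when an endpoint sequence is constant.
    """
    deg = degree_sequences(g)
    i_idx, j_idx = np.nonzero(g.counts)
    if i_idx.size == 0:
        return float("nan")
    mult = g.counts[i_idx, j_idx]
    if g.directed:
        x = np.repeat(deg.k_out[i_idx], mult).astype(float)
        y = np.repeat(deg.k_in[j_idx], mult).astype(float)
    else:
        # the symmetric count matrix already lists both orientations, and
        # the doubled diagonal enters loops twice, as in the standard form
        x = np.repeat(deg.k_out[i_idx], mult).astype(float)
        y = np.repeat(deg.k_out[j_idx], mult).astype(float)
    if x.std() == 0.0 or y.std() == 0.0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def graph_stats(g: MultiGraph, reference: DegreeSequence) -> GraphStats:
    """All per-realisation statistics in one pass."""
    return GraphStats(
        m=g.m,
        degree_mse=degree_mse(g, reference),
        centralization=centralization(g),
        assortativity=assortativity(g),
    )


def _bootstrap_var_less(
    x: np.ndarray, y: np.ndarray, n_boot: int, rng: np.random.Generator
) -> float:
    """One-sided bootstrap-t p-value for H1: Var[x] < Var[y].

    The statistic is the variance difference, studentised by its bootstrap
    standard error; the p-value is the bootstrap tail probability of the
    null (shifted) distribution at the observed statistic.
    """
    theta = np.var(y, ddof=1) - np.var(x, ddof=1)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        xb = rng.choice(x, size=x.size, replace=True)
        yb = rng.choice(y, size=y.size, replace=True)
        reps[b] = np.var(yb, ddof=1) - np.var(xb, ddof=1)
    se = reps.std(ddof=1)
    if se == 0.0:
        return 0.0 if theta > 0 else 1.0
    t_obs = theta / se
    t_null = (reps - theta) / se
    return float(np.mean(t_null >= t_obs))


def _sample_model(
    kind: str, reference: MultiGraph, n_samples: int, seed
) -> Iterable[MultiGraph]:
    deg = degree_sequences(reference)
    if kind == "cm":
        return cm_stub_matching_sample(deg, n_samples, seed)
    if kind == "hype":
        return HypeModel.from_degrees(deg).sample(n_samples, seed)
    if kind == "chung-lu":
        return ChungLuModel.from_degrees(deg).sample(n_samples, seed)
    raise ValidationError(f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}")


def run_comparison(
    reference: MultiGraph,
    models: tuple[str, ...] = MODEL_KINDS,
    n_samples: int = 2000,
    seed=0,
    n_boot: int = 2000,
) -> EnsembleSummary:
    """Sample each model induced by ``reference`` and contrast the ensembles.

    Default scale is 2,000 realisations per model, which resolves the
    qualitative ordering of the models on a ~50-vertex reference; larger
    runs are a parameter away.
    """
    rng = np.random.default_rng(seed)
    ref_deg = degree_sequences(reference)
    summary = EnsembleSummary(stats={})
    for kind in models:
        sub_seed = rng.integers(2**31)
        graphs = _sample_model(kind, reference, n_samples, sub_seed)
        summary.stats[kind] = [graph_stats(g, ref_deg) for g in graphs]

    def finite(model: str, name: str) -> np.ndarray:
        vals = summary.arrays(model, name)
        return vals[np.isfinite(vals)]

    if "hype" in summary.stats and "chung-lu" in summary.stats:
        t, p = stats.ttest_ind(
            summary.arrays("hype", "degree_mse"),
            summary.arrays("chung-lu", "degree_mse"),
            equal_var=False,
            alternative="less",
        )
        summary.contrasts.append(
            {
                "statistic": "degree_mse",
                "pair": ["hype", "chung-lu"],
                "test": "welch-t one-sided (hype < chung-lu)",
                "p_value": float(p),
                "direction": "hype smaller" if t < 0 else "hype larger",
            }
        )
        p_boot = _bootstrap_var_less(
            finite("hype", "centralization"),
            finite("chung-lu", "centralization"),
            n_boot,
            rng,
        )
        summary.contrasts.append(
            {
                "statistic": "centralization_variance",
                "pair": ["hype", "chung-lu"],
                "test": "bootstrap-t one-sided (Var hype < Var chung-lu)",
                "p_value": p_boot,
                "direction": "hype smaller variance" if p_boot < 0.5 else "inconclusive",
            }
        )
    for model in summary.stats:
        vals = summary.arrays(model, "assortativity")
        summary.dropped_assortativity[model] = int(np.sum(~np.isfinite(vals)))
    names = list(summary.stats)
    for a_i in range(len(names)):
        for b_i in range(a_i + 1, len(names)):
            a, b = names[a_i], names[b_i]
            xs, ys = finite(a, "assortativity"), finite(b, "assortativity")
            if xs.size == 0 or ys.size == 0:
                continue
            ks, p = stats.ks_2samp(xs, ys)
            summary.contrasts.append(
                {
                    "statistic": "assortativity",
                    "pair": [a, b],
                    "test": "ks two-sided",
                    "p_value": float(p),
                    "direction": "distributions differ" if p < 0.05 else "similar",
                }
            )
    return summary
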