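import numpy as np
import pytest

from ghype import DegreeSequence, HypeModel, MultiGraph
from ghype.oracle import _support


@pytest.fixture
def two_cycle():
    """Directed 2-cycle on the toy model with k_out = k_in = (1, 1)."""
    return MultiGraph(counts=np.array([[0, 1], [1, 0]]), directed=True)


@pytest.fixture
def toy_directed_model():
    return HypeModel.from_degrees(DegreeSequence(k_out=[1, 1], k_in=[1, 1]))


@pytest.fixture
def toy_undirected_model():
    return HypeModel.from_degrees(DegreeSequence.undirected([1, 1]))


def enumerate_model_support(model):
    """All multigraphs with positive probability under a small HypE model."""
    counts = model.xi.urn_counts
    draws_list = _support(tuple(int(c) for c in counts), model.m, cap=10**6)
    return [model.xi.draws_to_graph(np.array(d)) for d in draws_list]


def variance_se(samples: np.ndarray) -> float:
    """Monte-Carlo standard error of the sample variance (4th-moment form)."""
    n = samples.size
    s2 = samples.var(ddof=1)
    m4 = np.mean((samples - samples.mean()) ** 4)
    var_of_var = (m4 - s2**2 * (n - 3) / (n - 1)) / n
    return float(np.sqrt(max(var_of_var, 0.0)))


def gof_pvalue(observed_counts: dict, probabilities: dict, n_draws: int) -> float:
    """Chi-square goodness-of-fit p-value of sampled outcome frequencies."""
    from scipy import stats

    keys = sorted(probabilities)
    f_obs = np.array([observed_counts.get(k, 0) for k in keys], dtype=float)
    f_exp = np.array([float(probabilities[k]) * n_draws for k in keys])
    keep = f_exp > 0
    return float(stats.chisquare(f_obs[keep], f_exp[keep]).pvalue)
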