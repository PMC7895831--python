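import numpy as np
import pytest

from kinising import (
    ExactDistribution,
    SKEnsembleSpec,
    rescale,
    sample_sk,
    sample_trajectories,
)

#: Critical inverse temperature of the default SK ensemble
#: (H0=0.5, J0=1, Jsigma=0.1), used to place tests in the
#: maximally fluctuating regime.
BETA_C = 1.1108


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    """One pinned asymmetric SK instance with N=4 at beta=1."""
    return sample_sk(SKEnsembleSpec(N=4), seed=7)


@pytest.fixture
def critical_params_n5():
    """N=5 instance rescaled to the critical inverse temperature."""
    base = sample_sk(SKEnsembleSpec(N=5), seed=3)
    return rescale(base, BETA_C)


@pytest.fixture
def tiny_ensemble(small_params):
    s0 = np.ones(small_params.N, dtype=np.int8)
    return sample_trajectories(small_params, s0, T=6, R=50, seed=99)


def product_distribution(m):
    return ExactDistribution.product(np.asarray(m))


def exact_prev_moments(params, p_prev):
    """Exact (m, C) of a 2^N distribution, for feeding approximations."""
    from kinising.core_model import enumerate_states

    S = enumerate_states(p_prev.N).astype(float)
    m = S.T @ p_prev.p
    C = (S.T * p_prev.p) @ S - np.outer(m, m)
    return m, C
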