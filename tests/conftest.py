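import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import norm

from somnostate import HmmParams


def enumerate_paths(k: int, n: int) -> np.ndarray:
    """All k**n hidden-state paths of length n, shape (k**n, n)."""
    grids = np.meshgrid(*([np.arange(k)] * n), indexing="ij")
    return np.stack(grids).reshape(n, -1).T


def brute_force_path_logprobs(params: HmmParams, obs) -> tuple[np.ndarray, np.ndarray]:
    """Joint log-probability of every possible path (exhaustive oracle)."""
    obs = np.asarray(obs, dtype=float)
    paths = enumerate_paths(params.k, len(obs))
    with np.errstate(divide="ignore"):
        logpi = np.log(params.pi)
        logA = np.log(params.A)
    lp = logpi[paths[:, 0]]
    if paths.shape[1] > 1:
        lp = lp + logA[paths[:, :-1], paths[:, 1:]].sum(axis=1)
    lp = lp + norm.logpdf(obs, params.mu[paths], params.sigma[paths]).sum(axis=1)
    return paths, lp


def brute_force_loglik(params: HmmParams, obs) -> float:
    _, lp = brute_force_path_logprobs(params, obs)
    return float(logsumexp(lp))


def brute_force_viterbi(params: HmmParams, obs) -> np.ndarray:
    paths, lp = brute_force_path_logprobs(params, obs)
    return paths[int(np.argmax(lp))]


def random_params(rng: np.random.Generator, k: int) -> HmmParams:
    """A random valid parameterization with continuous (tie-free) values."""
    return HmmParams(
        pi=rng.dirichlet(np.ones(k)),
        A=np.stack([rng.dirichlet(np.ones(k)) for _ in range(k)]),
        mu=rng.normal(0.0, 2.0, k),
        sigma=rng.uniform(0.5, 2.0, k),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
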