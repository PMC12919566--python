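"""HMM core: likelihood, EM, Viterbi, criteria, relabeling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from somnostate import (
    HmmParams,
    em_fit,
    free_parameter_count,
    information_criteria,
    log_likelihood,
    relabel_by_mean,
    viterbi_decode,
)
from somnostate.hmm_core import DEFAULT_SD_FLOOR

from conftest import brute_force_loglik, brute_force_viterbi, random_params


def test_single_observation_closed_form():
    # deterministic start in a standard-normal state: loglik = log phi(0)
    p = HmmParams(np.array([1.0, 0.0]), np.eye(2),
                  np.array([0.0, 10.0]), np.array([1.0, 1.0]))
    assert log_likelihood(p, [0.0]) == pytest.approx(
        math.log(1.0 / math.sqrt(2 * math.pi)), abs=1e-12)


@pytest.mark.parametrize("k,n", [(2, 5), (3, 6), (3, 8), (2, 2)])
def test_loglik_and_viterbi_match_enumeration(rng, k, n):
    for _ in range(10):
        p = random_params(rng, k)
        obs = rng.normal(0.0, 2.0, n)
        assert log_likelihood(p, obs) == pytest.approx(
            brute_force_loglik(p, obs), abs=1e-8)
        assert np.array_equal(viterbi_decode(p, obs),
                              brute_force_viterbi(p, obs))


def test_loglik_translation_invariance(rng):
    p = random_params(rng, 3)
    obs = rng.normal(0.0, 2.0, 50)
    shifted = HmmParams(p.pi, p.A, p.mu + 7.5, p.sigma)
    assert log_likelihood(p, obs) == pytest.approx(
        log_likelihood(shifted, obs + 7.5), rel=1e-12)


def test_loglik_matches_hmmlearn(rng):
    # independent implementation as an oracle on a longer sequence
    from hmmlearn.hmm import GaussianHMM

    p = random_params(rng, 3)
    obs = rng.normal(0.0, 2.0, 300)
    ref = GaussianHMM(n_components=3, covariance_type="diag", init_params="")
    ref.startprob_ = p.pi
    ref.transmat_ = p.A
    ref.means_ = p.mu[:, None]
    ref.covars_ = (p.sigma ** 2)[:, None]
    assert log_likelihood(p, obs) == pytest.approx(
        ref.score(obs[:, None]), abs=1e-7)
    assert np.array_equal(viterbi_decode(p, obs), ref.predict(obs[:, None]))


def test_viterbi_separated_emissions():
    p = HmmParams(np.array([0.5, 0.5]),
                  np.array([[0.6, 0.4], [0.4, 0.6]]),
                  np.array([100.0, 0.0]), np.array([0.1, 0.1]))
    assert viterbi_decode(p, [100.0, 0.0, 100.0]).tolist() == [0, 1, 0]


def test_viterbi_absorbing_start(rng):
    p = HmmParams(np.array([0.0, 0.0, 1.0]), np.eye(3),
                  np.array([3.0, 1.5, 0.0]), np.array([1.0, 1.0, 1.0]))
    obs = rng.normal(2.0, 3.0, 20)
    assert np.all(viterbi_decode(p, obs) == 2)


def test_nonfinite_observation_rejected(rng):
    p = random_params(rng, 2)
    with pytest.raises(ValueError, match="finite"):
        log_likelihood(p, [0.0, np.nan])


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------

def _two_cluster_day(rng, mu=(0.0, 50.0), sigma=1.0, n_half=720):
    obs = np.concatenate([
        rng.normal(mu[0], sigma, n_half), rng.normal(mu[1], sigma, n_half)])
    init = HmmParams(np.array([0.5, 0.5]), np.full((2, 2), 0.5),
                     np.array([10.0, 40.0]), np.array([5.0, 5.0]))
    return obs, init


def test_em_recovers_separated_means(rng):
    obs, init = _two_cluster_day(rng)
    fit = em_fit(obs, init)
    assert fit.converged
    mu_sorted = np.sort(fit.params.mu)
    assert abs(mu_sorted[0] - 0.0) < 0.5
    assert abs(mu_sorted[1] - 50.0) < 0.5


def test_em_loglik_monotone(rng):
    obs, init = _two_cluster_day(rng)
    fit = em_fit(obs, init)
    assert np.all(np.diff(fit.loglik_trace) >= -1e-10)


def test_em_constant_input_degenerate():
    obs = np.full(100, 3.0)
    init = HmmParams(np.array([0.5, 0.5]), np.full((2, 2), 0.5),
                     np.array([2.0, 4.0]), np.array([1.0, 1.0]))
    fit = em_fit(obs, init)
    assert fit.degenerate
    # the occupied state's SD collapses onto the floor
    assert np.min(fit.params.sigma) == pytest.approx(DEFAULT_SD_FLOOR)


@pytest.mark.parametrize("max_iter", [1, 2, 5, 20])
def test_em_constraints_after_every_m_step(rng, max_iter):
    # stopping after any number of cycles must leave valid parameters
    obs, init = _two_cluster_day(rng)
    fit = em_fit(obs, init, max_iter=max_iter)
    fit.params.validate(sd_floor=DEFAULT_SD_FLOOR)


def test_em_rejects_too_short_sequence(rng):
    init = random_params(rng, 3)
    with pytest.raises(ValueError, match="more observations"):
        em_fit(np.zeros(3), init)


def test_fit_result_criteria_consistency(rng):
    obs, init = _two_cluster_day(rng)
    fit = em_fit(obs, init)
    p, n = fit.n_free_params, fit.n_obs
    assert fit.aic == pytest.approx(2 * p - 2 * fit.loglik)
    assert fit.bic == pytest.approx(p * math.log(n) - 2 * fit.loglik)


# ---------------------------------------------------------------------------
# Parameter counting and information criteria
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("k,expected", [(2, 7), (3, 14), (4, 23), (5, 34)])
def test_free_parameter_count(k, expected):
    assert free_parameter_count(k) == expected


def test_free_parameter_count_rejects_nonpositive():
    with pytest.raises(ValueError):
        free_parameter_count(0)


def test_information_criteria_edge():
    assert information_criteria(0.0, 0, 1) == (0.0, 0.0)
    with pytest.raises(ValueError):
        information_criteria(0.0, 1, 0)


# ---------------------------------------------------------------------------
# Relabeling
# ---------------------------------------------------------------------------

def test_relabel_orders_means_descending():
    p = HmmParams(np.array([0.2, 0.5, 0.3]),
                  np.full((3, 3), 1 / 3),
                  np.array([5.0, 80.0, 0.1]), np.array([1.0, 2.0, 3.0]))
    newp, path = relabel_by_mean(p, np.array([1, 0, 2]))
    assert newp.mu.tolist() == [80.0, 5.0, 0.1]
    assert path.tolist() == [0, 1, 2]  # old state 1 -> new state 0


def test_relabel_identity_when_sorted():
    p = HmmParams(np.array([0.5, 0.5]), np.full((2, 2), 0.5),
                  np.array([10.0, 1.0]), np.array([1.0, 1.0]))
    newp = relabel_by_mean(p)
    assert np.array_equal(newp.mu, p.mu)


def test_relabel_tie_breaks_on_sigma():
    p = HmmParams(np.array([0.5, 0.5]), np.full((2, 2), 0.5),
                  np.array([3.0, 3.0]), np.array([1.0, 2.0]))
    newp = relabel_by_mean(p)
    assert newp.sigma.tolist() == [2.0, 1.0]


def test_relabel_preserves_likelihood(rng):
    p = random_params(rng, 4)
    obs = rng.normal(0.0, 2.0, 40)
    newp = relabel_by_mean(p)
    assert log_likelihood(newp, obs) == pytest.approx(
        log_likelihood(p, obs), rel=1e-12)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(seed=st.integers(0, 10_000), k=st.integers(2, 4))
def test_relabel_involution_property(seed, k):
    # relabeling an already-relabeled model changes nothing
    r = np.random.default_rng(seed)
    p = random_params(r, k)
    once = relabel_by_mean(p)
    twice = relabel_by_mean(once)
    assert np.array_equal(once.mu, twice.mu)
    assert np.array_equal(once.A, twice.A)


def test_params_text_round_trip(rng):
    p = random_params(rng, 3)
    q = HmmParams.from_text(p.to_text())
    for attr in ("pi", "A", "mu", "sigma"):
        assert np.array_equal(getattr(p, attr), getattr(q, attr))


def test_params_validation_catches_bad_rows():
    with pytest.raises(ValueError, match="sum"):
        HmmParams(np.array([0.5, 0.5]),
                  np.array([[0.9, 0.2], [0.5, 0.5]]),
                  np.array([1.0, 0.0]), np.array([1.0, 1.0])).validate()
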