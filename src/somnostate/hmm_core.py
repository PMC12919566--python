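"""Gaussian-emission hidden Markov model mathematics.

This module implements the numerical core of the sleep-state pipeline: the
forward log-likelihood, Baum-Welch (EM) parameter estimation, Viterbi
decoding, free-parameter counting, AIC/BIC, and the canonical relabeling
that orders hidden states by decreasing emission mean (state 0 = most
active, state k-1 = most quiescent).

The model: a k-state homogeneous Markov chain with initial distribution pi
and row-stochastic transition matrix A, emitting at each minute a real
observation from a state-specific univariate Gaussian N(mu_j, sigma_j**2).
Observations are normalized per-minute activity values on a 0-100 scale.

All recursions run inside numba-compiled kernels.  The forward-backward
pass uses per-timestep scaled linear-space arithmetic with an additional
per-timestep rescaling of the emission densities (the rescaling constants
are re-absorbed into the log-likelihood), which is numerically equivalent
to a log-space implementation over 1440-point sequences; Viterbi runs in
log space, where max-product becomes max-sum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "HmmParams",
    "FitResult",
    "log_likelihood",
    "em_fit",
    "viterbi_decode",
    "free_parameter_count",
    "information_criteria",
    "relabel_by_mean",
]

#: Default lower bound for emission standard deviations.  Whole-minute
#: zero runs drive the quiescent state's variance toward 0; the floor
#: keeps the likelihood finite while still allowing a near-degenerate
#: "all-zero" sleep state.
DEFAULT_SD_FLOOR = 1e-6

#: Default relative log-likelihood change declaring EM convergence.
DEFAULT_TOL = 1e-8

#: Default cap on EM cycles within a single fit.
DEFAULT_MAX_ITER = 500

_LOG_2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass
class HmmParams:
    """Parameters of a k-state Gaussian-emission HMM.

    Attributes
    ----------
    pi : (k,) initial state distribution.
    A : (k, k) row-stochastic transition matrix; ``A[i, j]`` is the
        probability of moving from state i to state j in one minute.
    mu : (k,) emission means, in normalized-activity units.
    sigma : (k,) emission standard deviations, same units, all > 0.
    """

    pi: np.ndarray
    A: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)

    @property
    def k(self) -> int:
        return self.pi.shape[0]

    def validate(self, sd_floor: float = 0.0) -> None:
        """Raise ``ValueError`` if any simplex/stochasticity/positivity
        constraint is violated."""
        k = self.k
        if k < 2:
            raise ValueError(f"need at least 2 states, got k={k}")
        if self.A.shape != (k, k) or self.mu.shape != (k,) or self.sigma.shape != (k,):
            raise ValueError("inconsistent parameter shapes")
        if np.any(self.pi < 0) or np.any(self.A < 0):
            raise ValueError("negative probabilities")
        if abs(self.pi.sum() - 1.0) > 1e-12:
            raise ValueError(f"pi sums to {self.pi.sum()!r}, not 1")
        rows = self.A.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-12):
            raise ValueError("transition matrix rows must sum to 1")
        if np.any(self.sigma < max(sd_floor, 0.0)) or np.any(self.sigma <= 0):
            raise ValueError("emission SDs must be positive (>= sd_floor)")
        if not (np.all(np.isfinite(self.mu)) and np.all(np.isfinite(self.sigma))):
            raise ValueError("non-finite emission parameters")

    def copy(self) -> "HmmParams":
        return HmmParams(self.pi.copy(), self.A.copy(), self.mu.copy(), self.sigma.copy())

    # -- plain-text round trip ------------------------------------------------

    def to_text(self) -> str:
        """Serialize to a plain-text key-value document (reproducibility log)."""
        lines = [f"k = {self.k}"]
        lines.append("pi = " + " ".join(repr(float(v)) for v in self.pi))
        for i, row in enumerate(self.A):
            lines.append(f"A{i} = " + " ".join(repr(float(v)) for v in row))
        lines.append("mu = " + " ".join(repr(float(v)) for v in self.mu))
        lines.append("sigma = " + " ".join(repr(float(v)) for v in self.sigma))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "HmmParams":
        kv: dict[str, str] = {}
        for line in text.strip().splitlines():
            key, _, val = line.partition("=")
            kv[key.strip()] = val.strip()
        k = int(kv["k"])
        pi = np.array([float(v) for v in kv["pi"].split()])
        A = np.array([[float(v) for v in kv[f"A{i}"].split()] for i in range(k)])
        mu = np.array([float(v) for v in kv["mu"].split()])
        sigma = np.array([float(v) for v in kv["sigma"].split()])
        return cls(pi, A, mu, sigma)


@dataclass
class FitResult:
    """Outcome of one EM fit on a single observation day."""

    params: HmmParams
    loglik: float
    n_em_iterations: int
    converged: bool
    aic: float
    bic: float
    n_free_params: int
    n_obs: int
    degenerate: bool = False
    #: per-iteration log-likelihood trace (E-step values), for diagnostics
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

# Observation sequences are passed to the kernels factored into their
# unique values ``u`` plus an index vector ``inv`` (obs[t] = u[inv[t]]).
# Normalized per-minute counts live on a small lattice (count / daily
# total), so emission densities need computing only once per distinct
# value per EM iteration — the dominant cost otherwise.

@njit(cache=True)
def _emission_tables(u, mu, sigma):
    """Per-unique-value log emission densities, rescaled per value.

    Returns (Bq, mq): Bq[q, j] = exp(logN(u[q]; mu_j, sigma_j) - mq[q])
    with mq[q] the per-value maximum, so each row's maximum is 1.  The
    subtracted mq re-enters the log-likelihood additively.
    """
    m_vals = u.shape[0]
    k = mu.shape[0]
    Bq = np.empty((m_vals, k))
    mq = np.empty(m_vals)
    for j in range(k):
        c = -math.log(sigma[j]) - 0.5 * _LOG_2PI
        inv2 = 0.5 / (sigma[j] * sigma[j])
        for q in range(m_vals):
            d = u[q] - mu[j]
            Bq[q, j] = c - d * d * inv2
    for q in range(m_vals):
        m = Bq[q, 0]
        for j in range(1, k):
            if Bq[q, j] > m:
                m = Bq[q, j]
        mq[q] = m
        for j in range(k):
            Bq[q, j] = math.exp(Bq[q, j] - m)
    return Bq, mq


@njit(cache=True)
def _forward_loglik(u, inv, A, pi, mu, sigma):
    """Scaled forward pass; returns log P(obs | params)."""
    Bq, mq = _emission_tables(u, mu, sigma)
    n = inv.shape[0]
    k = pi.shape[0]
    alpha = np.empty(k)
    nxt = np.empty(k)
    q = inv[0]
    s = 0.0
    for j in range(k):
        alpha[j] = pi[j] * Bq[q, j]
        s += alpha[j]
    loglik = math.log(s) + mq[q]
    for j in range(k):
        alpha[j] /= s
    for t in range(1, n):
        q = inv[t]
        s = 0.0
        for j in range(k):
            acc = 0.0
            for i in range(k):
                acc += alpha[i] * A[i, j]
            nxt[j] = acc * Bq[q, j]
            s += nxt[j]
        loglik += math.log(s) + mq[q]
        for j in range(k):
            alpha[j] = nxt[j] / s
    return loglik


@njit(cache=True)
def _em_run(u, inv, pi0, A0, mu0, sigma0, tol, max_iter, sd_floor):
    """Full Baum-Welch loop.  Returns (pi, A, mu, sigma, loglik, n_iter,
    converged, trace) where loglik is that of the returned parameters.

    One iteration: scaled forward pass storing alpha and the scale
    factors, then a backward sweep that accumulates the transition
    responsibilities (xi) and the per-unique-value state responsibilities
    (wq) on the fly, then the closed-form M-step from those statistics.
    """
    n = inv.shape[0]
    m_vals = u.shape[0]
    k = pi0.shape[0]
    pi = pi0.copy()
    A = A0.copy()
    mu = mu0.copy()
    sigma = sigma0.copy()
    trace = np.empty(max_iter)
    alpha = np.empty((n, k))
    scale = np.empty(n)
    beta = np.empty(k)
    beta_new = np.empty(k)
    gam = np.empty(k)
    wq = np.empty((m_vals, k))
    xi = np.empty((k, k))
    xi_sum = np.empty((k, k))
    ll_prev = -np.inf
    converged = False
    n_iter = 0
    for it in range(max_iter):
        Bq, mq = _emission_tables(u, mu, sigma)
        # forward
        q = inv[0]
        s = 0.0
        for j in range(k):
            alpha[0, j] = pi[j] * Bq[q, j]
            s += alpha[0, j]
        scale[0] = s
        ll = math.log(s) + mq[q]
        for j in range(k):
            alpha[0, j] /= s
        for t in range(1, n):
            q = inv[t]
            s = 0.0
            for j in range(k):
                acc = 0.0
                for i in range(k):
                    acc += alpha[t - 1, i] * A[i, j]
                alpha[t, j] = acc * Bq[q, j]
                s += alpha[t, j]
            scale[t] = s
            ll += math.log(s) + mq[q]
            for j in range(k):
                alpha[t, j] /= s
        trace[it] = ll
        n_iter = it + 1
        if it > 0:
            denom = abs(ll_prev)
            if denom < 1.0:
                denom = 1.0
            if abs(ll - ll_prev) / denom < tol:
                converged = True
                break
        ll_prev = ll
        # backward + responsibility accumulation
        for q in range(m_vals):
            for j in range(k):
                wq[q, j] = 0.0
        for i in range(k):
            for j in range(k):
                xi_sum[i, j] = 0.0
        for j in range(k):
            beta[j] = 1.0
            wq[inv[n - 1], j] += alpha[n - 1, j]
        for t in range(n - 2, -1, -1):
            qn = inv[t + 1]
            s = 0.0
            for i in range(k):
                for j in range(k):
                    xi[i, j] = alpha[t, i] * A[i, j] * Bq[qn, j] * beta[j]
                    s += xi[i, j]
            for i in range(k):
                for j in range(k):
                    xi_sum[i, j] += xi[i, j] / s
            for i in range(k):
                acc = 0.0
                for j in range(k):
                    acc += A[i, j] * Bq[qn, j] * beta[j]
                beta_new[i] = acc / scale[t + 1]
            sg = 0.0
            for i in range(k):
                beta[i] = beta_new[i]
                gam[i] = alpha[t, i] * beta[i]
                sg += gam[i]
            q = inv[t]
            for i in range(k):
                gam[i] /= sg
                wq[q, i] += gam[i]
        # M-step
        for j in range(k):
            pi[j] = gam[j]  # gamma at t = 0
        for i in range(k):
            s = 0.0
            for j in range(k):
                s += xi_sum[i, j]
            if s > 0.0:
                for j in range(k):
                    A[i, j] = xi_sum[i, j] / s
        for j in range(k):
            w = 0.0
            wx = 0.0
            for q in range(m_vals):
                w += wq[q, j]
                wx += wq[q, j] * u[q]
            if w > 1e-300:
                m_j = wx / w
                wv = 0.0
                for q in range(m_vals):
                    d = u[q] - m_j
                    wv += wq[q, j] * d * d
                mu[j] = m_j
                s_j = math.sqrt(wv / w)
                sigma[j] = s_j if s_j > sd_floor else sd_floor
    # log-likelihood of the parameters actually returned
    ll_final = _forward_loglik(u, inv, A, pi, mu, sigma)
    return pi, A, mu, sigma, ll_final, n_iter, converged, trace[:n_iter]


@njit(cache=True)
def _viterbi(u, inv, logA, logpi, mu, sigma):
    """Max-sum Viterbi in log space; ties broken toward the lower state
    index at every comparison (strict > keeps the first maximum)."""
    n = inv.shape[0]
    m_vals = u.shape[0]
    k = logpi.shape[0]
    logBq = np.empty((m_vals, k))
    for j in range(k):
        c = -math.log(sigma[j]) - 0.5 * _LOG_2PI
        inv2 = 0.5 / (sigma[j] * sigma[j])
        for q in range(m_vals):
            d = u[q] - mu[j]
            logBq[q, j] = c - d * d * inv2
    delta = np.empty((n, k))
    psi = np.zeros((n, k), dtype=np.int64)
    for j in range(k):
        delta[0, j] = logpi[j] + logBq[inv[0], j]
    for t in range(1, n):
        q = inv[t]
        for j in range(k):
            best = delta[t - 1, 0] + logA[0, j]
            arg = 0
            for i in range(1, k):
                v = delta[t - 1, i] + logA[i, j]
                if v > best:
                    best = v
                    arg = i
            delta[t, j] = best + logBq[q, j]
            psi[t, j] = arg
    path = np.empty(n, dtype=np.int64)
    best = delta[n - 1, 0]
    arg = 0
    for j in range(1, k):
        if delta[n - 1, j] > best:
            best = delta[n - 1, j]
            arg = j
    path[n - 1] = arg
    for t in range(n - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def _check_obs(obs) -> np.ndarray:
    obs = np.ascontiguousarray(obs, dtype=float)
    if obs.ndim != 1 or obs.shape[0] < 1:
        raise ValueError("observations must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(obs)):
        raise ValueError("observations must be finite")
    return obs


def _factor_obs(obs) -> tuple[np.ndarray, np.ndarray]:
    u, inv = np.unique(obs, return_inverse=True)
    return np.ascontiguousarray(u), np.ascontiguousarray(inv.astype(np.int64))


def log_likelihood(params: HmmParams, obs) -> float:
    """Log P(obs | params) via the scaled forward recursion."""
    obs = _check_obs(obs)
    params.validate()
    u, inv = _factor_obs(obs)
    return float(_forward_loglik(
        u, inv, np.ascontiguousarray(params.A, dtype=float),
        np.ascontiguousarray(params.pi, dtype=float),
        np.ascontiguousarray(params.mu, dtype=float),
        np.ascontiguousarray(params.sigma, dtype=float),
    ))


def em_fit(
    obs,
    init: HmmParams,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    sd_floor: float = DEFAULT_SD_FLOOR,
) -> FitResult:
    """Baum-Welch estimation of a Gaussian HMM from one observation day.

    E-steps compute forward-backward state/transition responsibilities;
    M-steps apply the closed-form updates for pi, A, mu and sigma, with
    sigma clipped below at ``sd_floor``.  The loop stops when the relative
    change in log-likelihood drops below ``tol`` (converged) or after
    ``max_iter`` cycles.  The per-iteration log-likelihoods are
    non-decreasing up to roundoff; the trace is kept on the result.

    AIC/BIC are computed with p = free_parameter_count(k) and n = len(obs).
    """
    obs = _check_obs(obs)
    init.validate()
    k = init.k
    n = obs.shape[0]
    if n <= k:
        raise ValueError(f"need more observations than states (n={n}, k={k})")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    sigma0 = np.maximum(init.sigma, sd_floor)
    u, inv = _factor_obs(obs)
    pi, A, mu, sigma, ll, n_iter, converged, trace = _em_run(
        u,
        inv,
        np.ascontiguousarray(init.pi, dtype=float),
        np.ascontiguousarray(init.A, dtype=float),
        np.ascontiguousarray(init.mu, dtype=float),
        np.ascontiguousarray(sigma0, dtype=float),
        float(tol),
        int(max_iter),
        float(sd_floor),
    )
    degenerate = bool(np.ptp(obs) == 0.0)
    p = free_parameter_count(k)
    aic, bic = information_criteria(ll, p, n)
    return FitResult(
        params=HmmParams(pi, A, mu, sigma),
        loglik=float(ll),
        n_em_iterations=int(n_iter),
        converged=bool(converged),
        aic=aic,
        bic=bic,
        n_free_params=p,
        n_obs=n,
        degenerate=degenerate,
        loglik_trace=np.asarray(trace),
    )


def viterbi_decode(params: HmmParams, obs) -> np.ndarray:
    """Most probable joint hidden-state path (ties toward lower index)."""
    obs = _check_obs(obs)
    params.validate()
    u, inv = _factor_obs(obs)
    with np.errstate(divide="ignore"):
        logA = np.log(params.A)
        logpi = np.log(params.pi)
    return _viterbi(
        u, inv, np.ascontiguousarray(logA), np.ascontiguousarray(logpi),
        np.ascontiguousarray(params.mu, dtype=float),
        np.ascontiguousarray(params.sigma, dtype=float),
    )


def free_parameter_count(k: int) -> int:
    """Free parameters of a k-state Gaussian HMM.

    (k - 1) initial probabilities + k(k - 1) transition probabilities +
    k means + k standard deviations = k**2 + 2k - 1.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    return k * k + 2 * k - 1


def information_criteria(loglik: float, p: int, n: int) -> tuple[float, float]:
    """AIC = 2p - 2*loglik; BIC = p*ln(n) - 2*loglik."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if p < 0:
        raise ValueError("p must be >= 0")
    aic = 2.0 * p - 2.0 * loglik
    bic = p * math.log(n) - 2.0 * loglik
    return aic, bic


def relabel_by_mean(params: HmmParams, path=None):
    """Permute states so emission means are non-increasing with state index.

    State 0 becomes the most active state and state k-1 the most quiescent,
    matching the field convention for sleep staging.  Ties on the mean are
    broken toward the larger sigma, then the original index.  If ``path``
    is given, its labels are remapped consistently and the pair
    ``(params, path)`` is returned; otherwise only the parameters.
    """
    k = params.k
    # lexsort: last key is primary
    order = np.lexsort((np.arange(k), -params.sigma, -params.mu))
    new = HmmParams(
        params.pi[order],
        params.A[np.ix_(order, order)],
        params.mu[order],
        params.sigma[order],
    )
    if path is None:
        return new
    relabel = np.empty(k, dtype=np.int64)
    relabel[order] = np.arange(k)
    return new, relabel[np.asarray(path)]
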