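"""Per-fly per-day orchestration of the iterated HMM fit.

The EM likelihood surface for a whole day of activity has local maxima, so
a single fit is not trusted.  Instead each fly-day is fitted T times: the
first fit uses a structured transition initialization in which direct
transitions between the two extreme states (most active <-> most
quiescent) start at 1e-5, and every later fit redraws the initial state
distribution from a flat Dirichlet.  Each converged fit is Viterbi-decoded
and relabeled so state 0 is the most active; the per-minute modal state
across fits is the consensus sequence, and the ambiguity score
(1 - n/T) * 100 — where n is the multiplicity of the most frequent
whole-day sequence — quantifies how often the restarts disagreed.

Model order (the number of hidden states k) is chosen by fitting k in a
range (default 2-10) and taking the k minimizing BIC.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dam_io import FlyDay, MINUTES_PER_DAY
from .hmm_core import (
    DEFAULT_MAX_ITER,
    DEFAULT_SD_FLOOR,
    DEFAULT_TOL,
    FitResult,
    HmmParams,
    em_fit,
    relabel_by_mean,
    viterbi_decode,
)

logger = logging.getLogger("somnostate")

__all__ = [
    "IterationEnsemble",
    "ConsensusResult",
    "OrderSelectionTable",
    "normalize_day",
    "structured_transition_init",
    "draw_initial_distribution",
    "emission_init",
    "iterate_fit",
    "consensus_sequence",
    "ambiguity_score",
    "select_state_count",
    "substream",
    "fit_fly",
]

EXTREME_TRANSITION_P = 1e-5


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass
class IterationEnsemble:
    """T randomized-restart fits of one fly-day."""

    fly_id: str
    day_index: int
    k: int
    T: int
    paths: np.ndarray          # (T, n) relabeled Viterbi paths
    fits: list[FitResult]
    converged: np.ndarray      # (T,) bool

    @property
    def n_converged(self) -> int:
        return int(self.converged.sum())

    @property
    def excluded(self) -> bool:
        """True when no restart converged; the fly-day yields no phenotype."""
        return self.n_converged == 0


@dataclass
class ConsensusResult:
    """Per-minute modal state across converged restarts of one fly-day."""

    fly_id: str
    day_index: int
    k: int
    T: int
    consensus: np.ndarray       # (n,) state indices
    support: np.ndarray         # (n,) votes for the modal state
    ambiguity_pct: float
    n_modal_sequences: int
    phase: Optional[np.ndarray] = None


@dataclass
class OrderSelectionTable:
    """Information criteria over a range of candidate state counts."""

    table: pd.DataFrame         # columns: k, loglik, aic, bic, converged_frac
    best_k_by_bic: int


# ---------------------------------------------------------------------------
# Normalization and initialization
# ---------------------------------------------------------------------------

def normalize_day(raw_counts) -> Optional[np.ndarray]:
    """Normalize one day of counts to percent of the daily total.

    Each minute becomes 100 * count / total, so every fly-day sums to 100
    regardless of how active the individual was.  A day with zero total
    activity (or any missing minute) cannot be normalized and returns
    None; such days are excluded from fitting.
    """
    x = np.asarray(raw_counts, dtype=float)
    if x.ndim != 1 or x.shape[0] != MINUTES_PER_DAY:
        raise ValueError(f"expected {MINUTES_PER_DAY} minutes, got {x.shape}")
    if np.any(x[np.isfinite(x)] < 0):
        raise ValueError("negative activity count")
    if np.any(~np.isfinite(x)):
        logger.warning("day with missing minutes cannot be normalized")
        return None
    total = x.sum()
    if total == 0:
        logger.warning("all-zero day cannot be normalized")
        return None
    return 100.0 * x / total


def structured_transition_init(k: int) -> np.ndarray:
    """Structured first-iteration transition matrix.

    Direct transitions between the two extreme states (index 0, most
    active, and index k-1, most quiescent) are set to 1e-5; the remaining
    mass in those rows is shared equally, and all other rows are uniform.
    For k = 2 the matrix is uniform (there are no intermediate states).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    A = np.full((k, k), 1.0 / k)
    if k >= 3:
        share = (1.0 - EXTREME_TRANSITION_P) / (k - 1)
        A[0, :] = share
        A[0, k - 1] = EXTREME_TRANSITION_P
        A[k - 1, :] = share
        A[k - 1, 0] = EXTREME_TRANSITION_P
    return A


def draw_initial_distribution(k: int, rng: np.random.Generator) -> np.ndarray:
    """Flat-Dirichlet draw of an initial state distribution."""
    if k < 2:
        raise ValueError("k must be >= 2")
    return rng.dirichlet(np.ones(k))


def emission_init(
    obs, k: int, sd_floor: float = DEFAULT_SD_FLOOR
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic emission starting values.

    Means sit at the (k-i)/(k+1) quantiles of the day's normalized
    activity, descending with state index so index 0 starts as the most
    active state; all SDs start at the day's sample SD (floored).
    """
    obs = np.asarray(obs, dtype=float)
    qs = np.array([(k - i) / (k + 1) for i in range(k)])
    mu = np.quantile(obs, qs)
    sd = max(float(np.std(obs)), sd_floor)
    return mu, np.full(k, sd)


def substream(seed: int, fly_id: str, day_index: int) -> np.random.Generator:
    """Deterministic per-fly-day random stream derived from one global seed.

    Keyed by a CRC32 of the fly id and the day index, so results do not
    depend on processing order."""
    key = zlib.crc32(str(fly_id).encode())
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), key, int(day_index)])
    )


# ---------------------------------------------------------------------------
# Iterated fitting, consensus, ambiguity
# ---------------------------------------------------------------------------

def iterate_fit(
    day: FlyDay,
    k: int,
    T: int,
    rng: np.random.Generator,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    sd_floor: float = DEFAULT_SD_FLOOR,
    jitter_emissions: float = 0.0,
) -> IterationEnsemble:
    """Fit one fly-day T times with randomized restarts.

    Restart 1 uses the structured transition matrix and a uniform initial
    distribution; restarts 2..T redraw the initial distribution from a
    flat Dirichlet (transition and emission starting values unchanged).
    ``jitter_emissions`` > 0 additionally perturbs the restart emission
    means by zero-mean Gaussian noise of that SD (in units of the day's
    sample SD) for users wanting more restart diversity.  Every fit is EM
    followed by Viterbi decoding and canonical relabeling.
    Non-convergent restarts are recorded but excluded from the consensus;
    an ensemble in which every restart failed is flagged excluded rather
    than raising.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if day.normalized is None:
        day.normalized = normalize_day(day.raw_counts)
    obs = day.normalized
    if obs is None:
        raise ValueError(
            f"{day.fly_id} day {day.day_index}: missing/all-zero day "
            "cannot be fitted"
        )
    A0 = structured_transition_init(k)
    mu0, sigma0 = emission_init(obs, k, sd_floor)
    n = obs.shape[0]
    paths = np.zeros((T, n), dtype=np.int64)
    fits: list[FitResult] = []
    converged = np.zeros(T, dtype=bool)
    obs_sd = max(float(np.std(obs)), sd_floor)
    for t in range(T):
        if t == 0:
            pi0 = np.full(k, 1.0 / k)
            mu_t = mu0
        else:
            pi0 = draw_initial_distribution(k, rng)
            mu_t = mu0
            if jitter_emissions > 0.0:
                mu_t = mu0 + rng.normal(0.0, jitter_emissions * obs_sd, k)
        init = HmmParams(pi0, A0, mu_t, sigma0)
        fit = em_fit(obs, init, tol=tol, max_iter=max_iter, sd_floor=sd_floor)
        path = viterbi_decode(fit.params, obs)
        fit.params, path = relabel_by_mean(fit.params, path)
        paths[t] = path
        fits.append(fit)
        converged[t] = fit.converged
    ens = IterationEnsemble(
        fly_id=day.fly_id, day_index=day.day_index, k=k, T=T,
        paths=paths, fits=fits, converged=converged,
    )
    if ens.excluded:
        logger.warning(
            "%s day %d: no restart converged; fly-day excluded",
            day.fly_id, day.day_index,
        )
    return ens


def consensus_sequence(ensemble: IterationEnsemble) -> ConsensusResult:
    """Per-minute modal state across converged restarts.

    Ties go to the lower (more active) state index.  The whole-day
    ambiguity score is attached.
    """
    if ensemble.n_converged == 0:
        raise ValueError("no converged restarts; no consensus exists")
    good = ensemble.paths[ensemble.converged]
    votes = np.apply_along_axis(
        np.bincount, 0, good, None, ensemble.k
    )  # (k, n)
    consensus = votes.argmax(axis=0)
    support = votes.max(axis=0)
    n_modal = _modal_multiplicity(good)
    amb = (1.0 - n_modal / ensemble.T) * 100.0
    return ConsensusResult(
        fly_id=ensemble.fly_id,
        day_index=ensemble.day_index,
        k=ensemble.k,
        T=ensemble.T,
        consensus=consensus.astype(np.int64),
        support=support.astype(np.int64),
        ambiguity_pct=float(amb),
        n_modal_sequences=int(n_modal),
    )


def _modal_multiplicity(paths: np.ndarray) -> int:
    _, counts = np.unique(paths, axis=0, return_counts=True)
    return int(counts.max())


def ambiguity_score(ensemble: IterationEnsemble) -> float:
    """(1 - n/T) * 100 with n the multiplicity of the most frequent
    whole-day decoded sequence among converged restarts.  0 means every
    restart agreed on the entire day."""
    if ensemble.T < 1:
        raise ValueError("T must be >= 1")
    if ensemble.n_converged == 0:
        return 100.0
    n = _modal_multiplicity(ensemble.paths[ensemble.converged])
    return (1.0 - n / ensemble.T) * 100.0


# ---------------------------------------------------------------------------
# Model-order selection
# ---------------------------------------------------------------------------

def select_state_count(
    day: FlyDay,
    k_min: int = 2,
    k_max: int = 10,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    sd_floor: float = DEFAULT_SD_FLOOR,
) -> OrderSelectionTable:
    """Fit every candidate k once (structured initialization) and rank by
    BIC.  Non-convergent candidates are kept in the table but excluded
    from the argmin; ties go to the smaller k."""
    if k_min < 2 or k_max < k_min:
        raise ValueError("need 2 <= k_min <= k_max")
    if day.normalized is None:
        day.normalized = normalize_day(day.raw_counts)
    obs = day.normalized
    if obs is None:
        raise ValueError("missing/all-zero day cannot be fitted")
    rows = []
    for k in range(k_min, k_max + 1):
        A0 = structured_transition_init(k)
        mu0, sigma0 = emission_init(obs, k, sd_floor)
        init = HmmParams(np.full(k, 1.0 / k), A0, mu0, sigma0)
        fit = em_fit(obs, init, tol=tol, max_iter=max_iter, sd_floor=sd_floor)
        rows.append({
            "k": k,
            "loglik": fit.loglik,
            "aic": fit.aic,
            "bic": fit.bic,
            "converged_frac": float(fit.converged),
        })
    table = pd.DataFrame(rows)
    ok = table[table["converged_frac"] > 0]
    if ok.empty:
        raise ValueError("no candidate state count converged")
    best = int(ok.loc[ok["bic"].idxmin(), "k"])
    return OrderSelectionTable(table=table, best_k_by_bic=best)


def aggregate_order_selection(
    tables: Sequence[OrderSelectionTable],
) -> OrderSelectionTable:
    """Average per-day selection tables (mean criteria, mean convergence
    fraction per k) into a per-fly table."""
    cat = pd.concat([t.table for t in tables], ignore_index=True)
    agg = (
        cat.groupby("k", as_index=False)
        .agg({"loglik": "mean", "aic": "mean", "bic": "mean",
              "converged_frac": "mean"})
        .sort_values("k", ignore_index=True)
    )
    ok = agg[agg["converged_frac"] > 0]
    best = int(ok.loc[ok["bic"].idxmin(), "k"])
    return OrderSelectionTable(table=agg, best_k_by_bic=best)


# ---------------------------------------------------------------------------
# Per-fly convenience driver
# ---------------------------------------------------------------------------

def fit_fly(
    days: Sequence[FlyDay],
    k: int = 4,
    T: int = 100,
    seed: int = 0,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    sd_floor: float = DEFAULT_SD_FLOOR,
) -> list[ConsensusResult]:
    """Run the iterated fit + consensus over a fly's analysis days.

    Days that cannot be normalized or whose ensembles have no converged
    restart are skipped (logged).  Each fly-day gets its own random
    substream keyed by (seed, fly_id, day_index).
    """
    results = []
    for day in days:
        if day.normalized is None:
            day.normalized = normalize_day(day.raw_counts)
        if day.normalized is None:
            continue
        rng = substream(seed, day.fly_id, day.day_index)
        ens = iterate_fit(
            day, k=k, T=T, rng=rng, tol=tol, max_iter=max_iter,
            sd_floor=sd_floor,
        )
        if ens.excluded:
            continue
        res = consensus_sequence(ens)
        res.phase = day.phase
        results.append(res)
    return results


def consensus_to_frame(results: Sequence[ConsensusResult]) -> pd.DataFrame:
    """Tidy consensus table (fly_id, day_index, zt_minute, state, support,
    T, ambiguity_pct) for export."""
    frames = []
    for r in results:
        frames.append(pd.DataFrame({
            "fly_id": r.fly_id,
            "day_index": r.day_index,
            "zt_minute": np.arange(len(r.consensus)),
            "state": r.consensus,
            "support": r.support,
            "T": r.T,
            "ambiguity_pct": r.ambiguity_pct,
        }))
    return pd.concat(frames, ignore_index=True)
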