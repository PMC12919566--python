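"""Synthetic data with known ground truth.

Generates the three kinds of inputs the pipeline consumes, from fully
specified generative models, so every downstream estimate can be scored
against truth:

* DAM-like activity: a k-state Markov chain with state-specific Poisson
  count intensities (integer beam-crossing counts per minute).  The
  inference model is Gaussian on normalized activity, so the generator
  deliberately stress-tests the same model misspecification real monitor
  data presents.  Defaults emulate active wake through deep sleep with
  intensities (3, 1, 0.3, 0.01) counts/minute and sticky (0.95 diagonal)
  transitions.
* DGRP-like phenotype panels: balanced line x sex x replicate layouts
  with independent Gaussian line, line-by-sex and residual effects of
  known variance.
* Arousal experiments: hourly progressive stimulus trains with
  state-conditional, level-dependent response probabilities.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dam_io import MINUTES_PER_DAY, N_CHANNELS, FlyDay, FlyMeta, MonitorTable
from .hmm_core import HmmParams
from .quantgen import PhenotypeRecord
from .quantify import DEFAULT_STIMULUS_LEVELS, StimulusTrain

__all__ = [
    "GeneratorSpec",
    "PanelSpec",
    "simulate_states",
    "simulate_counts",
    "simulate_fly_days",
    "simulate_gaussian_day",
    "simulate_monitor",
    "simulate_panel",
    "default_response_probs",
    "simulate_arousal",
]


@dataclass
class GeneratorSpec:
    """Generative model for one fly's activity: hidden Markov chain plus
    per-state Poisson count intensities (counts/minute, descending so
    state k-1 is the quiescent state)."""

    k: int = 4
    A_true: np.ndarray = None
    pi_true: np.ndarray = None
    count_intensity: np.ndarray = None
    days: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.A_true is None:
            self.A_true = sticky_transitions(self.k, 0.95)
        if self.pi_true is None:
            self.pi_true = np.full(self.k, 1.0 / self.k)
        if self.count_intensity is None:
            self.count_intensity = default_intensities(self.k)
        self.A_true = np.asarray(self.A_true, dtype=float)
        self.pi_true = np.asarray(self.pi_true, dtype=float)
        self.count_intensity = np.asarray(self.count_intensity, dtype=float)
        if np.any(np.diff(self.count_intensity) >= 0):
            raise ValueError("count intensities must be strictly descending")
        if np.any(self.count_intensity < 0):
            raise ValueError("count intensities must be non-negative")
        if abs(self.pi_true.sum() - 1) > 1e-9 or np.any(
            np.abs(self.A_true.sum(axis=1) - 1) > 1e-9
        ):
            raise ValueError("invalid chain parameters")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def sticky_transitions(k: int, diag: float = 0.95) -> np.ndarray:
    """Transition matrix with the given diagonal and the remaining mass
    shared equally among the other states."""
    A = np.full((k, k), (1.0 - diag) / (k - 1))
    np.fill_diagonal(A, diag)
    return A


def default_intensities(k: int) -> np.ndarray:
    """Expected counts/minute per state, active to quiescent."""
    if k == 4:
        return np.array([3.0, 1.0, 0.3, 0.01])
    return np.geomspace(3.0, 0.01, k)


def well_separated_gaussian(
    k: int = 4, spacing: float = 2.0, sigma: float = 0.4, diag: float = 0.95
) -> HmmParams:
    """A Gaussian HMM whose states are far apart relative to their spread
    (adjacent means ``spacing`` apart, common SD ``sigma``), with sticky
    transitions; the standard ground truth for order-selection studies."""
    mu = spacing * np.arange(k - 1, -1, -1, dtype=float)
    return HmmParams(
        np.full(k, 1.0 / k), sticky_transitions(k, diag), mu,
        np.full(k, float(sigma)),
    )


@dataclass
class PanelSpec:
    """Balanced inbred-line panel with known variance components.

    ``flies_per_line`` is the number of flies per line-sex cell."""

    n_lines: int = 100
    flies_per_line: int = 16
    sexes: int = 2
    sigma2_L: float = 1.0
    sigma2_SL: float = 0.5
    sigma2_E: float = 1.5
    grand_mean: float = 0.0
    seed: int = 0


# ---------------------------------------------------------------------------
# Activity generators
# ---------------------------------------------------------------------------

def simulate_states(
    spec: GeneratorSpec,
    n_minutes: int,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Sample a hidden-state path of length ``n_minutes`` from the spec's
    Markov chain (reproducible from spec.seed unless ``rng`` is given)."""
    if rng is None:
        rng = spec.rng()
    k = spec.k
    cum_pi = np.cumsum(spec.pi_true)
    cum_A = np.cumsum(spec.A_true, axis=1)
    u = rng.random(n_minutes)
    path = np.empty(n_minutes, dtype=np.int64)
    path[0] = np.searchsorted(cum_pi, u[0], side="right")
    for t in range(1, n_minutes):
        path[t] = np.searchsorted(cum_A[path[t - 1]], u[t], side="right")
    return np.minimum(path, k - 1)


def simulate_counts(
    path: np.ndarray,
    spec: GeneratorSpec,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Per-minute integer counts: Poisson draws with the state's intensity."""
    path = np.asarray(path)
    if path.max(initial=0) >= spec.k:
        raise ValueError("path contains states outside the spec")
    if rng is None:
        rng = spec.rng()
    lam = spec.count_intensity[path]
    return rng.poisson(lam).astype(np.int64)


def simulate_fly_days(
    spec: GeneratorSpec, fly_id: str = "fly"
) -> tuple[list[FlyDay], np.ndarray]:
    """Whole analysis days for one fly plus the true state path.

    Returns ``spec.days`` FlyDay objects (ZT-aligned, phase day for
    ZT < 720) and the concatenated true path, shape (days * 1440,).
    """
    rng = spec.rng()
    n = spec.days * MINUTES_PER_DAY
    truth = simulate_states(spec, n, rng)
    counts = simulate_counts(truth, spec, rng)
    zt = np.arange(MINUTES_PER_DAY)
    phase = np.where(zt < 720, "day", "night")
    days = []
    for d in range(spec.days):
        sl = slice(d * MINUTES_PER_DAY, (d + 1) * MINUTES_PER_DAY)
        days.append(FlyDay(
            fly_id=fly_id,
            day_index=d + 1,
            raw_counts=counts[sl].astype(float),
            zt_minute=zt.copy(),
            phase=phase.copy(),
        ))
    return days, truth


def simulate_gaussian_day(
    params: HmmParams, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Observations drawn exactly from a Gaussian-emission HMM (no count
    discretization); used to study model-order selection under the
    inference model's own assumptions."""
    k = params.k
    cum_pi = np.cumsum(params.pi)
    cum_A = np.cumsum(params.A, axis=1)
    u = rng.random(n)
    states = np.empty(n, dtype=np.int64)
    states[0] = np.searchsorted(cum_pi, u[0], side="right")
    for t in range(1, n):
        states[t] = np.searchsorted(cum_A[states[t - 1]], u[t], side="right")
    states = np.minimum(states, k - 1)
    obs = rng.normal(params.mu[states], params.sigma[states])
    return obs, states


def simulate_monitor(
    n_flies: int = 32,
    days: int = 6,
    monitor_id: str = "Monitor1",
    start: Optional[datetime] = None,
    base_spec: Optional[GeneratorSpec] = None,
    seed: int = 0,
    lights_on_hour: int = 8,
) -> tuple[MonitorTable, list[FlyMeta], pd.DataFrame]:
    """A full synthetic DAM2 monitor: up to 32 channels of simulated
    flies, metadata, and a truth table (fly_id, day, minute, true_state).

    Recording starts at lights-on so ZT days align with file rows."""
    if not 1 <= n_flies <= N_CHANNELS:
        raise ValueError(f"n_flies must be in [1, {N_CHANNELS}]")
    if base_spec is None:
        base_spec = GeneratorSpec()
    if start is None:
        start = datetime(2024, 1, 1, lights_on_hour, 0, 0)
    n_min = days * MINUTES_PER_DAY
    counts = np.zeros((n_min, N_CHANNELS), dtype=float)
    metas = []
    truth_rows = []
    for ch in range(1, n_flies + 1):
        spec = GeneratorSpec(
            k=base_spec.k,
            A_true=base_spec.A_true.copy(),
            pi_true=base_spec.pi_true.copy(),
            count_intensity=base_spec.count_intensity.copy(),
            days=days,
            seed=int(np.random.SeedSequence([seed, ch]).generate_state(1)[0] % (2**31)),
        )
        rng = spec.rng()
        truth = simulate_states(spec, n_min, rng)
        counts[:, ch - 1] = simulate_counts(truth, spec, rng)
        fly_id = f"{monitor_id}_ch{ch:02d}"
        metas.append(FlyMeta(
            fly_id=fly_id, monitor_id=monitor_id, channel=ch,
            genotype=f"line{(ch - 1) % 4 + 1}", sex="F" if ch % 2 else "M",
            block="b1", replicate="r1",
        ))
        truth_rows.append(pd.DataFrame({
            "fly_id": fly_id,
            "day": np.arange(n_min) // MINUTES_PER_DAY + 1,
            "minute": np.arange(n_min) % MINUTES_PER_DAY,
            "true_state": truth,
        }))
    times = pd.DatetimeIndex(
        [start + timedelta(minutes=int(m)) for m in range(n_min)]
    )
    table = MonitorTable(
        monitor_id=monitor_id,
        record_index=np.arange(1, n_min + 1),
        times=times,
        status=np.ones(n_min, dtype=int),
        counts=counts,
        missing=np.zeros(n_min, dtype=bool),
    )
    return table, metas, pd.concat(truth_rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Phenotype panel generator
# ---------------------------------------------------------------------------

def simulate_panel(spec: PanelSpec) -> list[PhenotypeRecord]:
    """Balanced panel with independent zero-mean Gaussian line,
    line-by-sex and residual effects of the spec's variances."""
    if spec.n_lines < 2:
        raise ValueError("need at least 2 lines")
    rng = np.random.default_rng(spec.seed)
    sexes = ["F", "M"][: spec.sexes]
    L = rng.normal(0.0, np.sqrt(spec.sigma2_L), spec.n_lines)
    SL = rng.normal(0.0, np.sqrt(spec.sigma2_SL), (spec.n_lines, len(sexes)))
    records = []
    fly = 0
    for li in range(spec.n_lines):
        line = f"L{li + 1:03d}"
        for si, sex in enumerate(sexes):
            e = rng.normal(0.0, np.sqrt(spec.sigma2_E), spec.flies_per_line)
            for ri in range(spec.flies_per_line):
                fly += 1
                records.append(PhenotypeRecord(
                    fly_id=f"fly{fly:05d}",
                    genotype=line,
                    sex=sex,
                    block="b1",
                    replicate=f"r{ri % 4 + 1}",
                    value=spec.grand_mean + L[li] + SL[li, si] + e[ri],
                ))
    return records


# ---------------------------------------------------------------------------
# Arousal experiment generator
# ---------------------------------------------------------------------------

def default_response_probs(
    k: int = 4, n_levels: int = len(DEFAULT_STIMULUS_LEVELS)
) -> np.ndarray:
    """State x level response probabilities: rise with stimulus level and
    fall with sleep depth, so deeper states need stronger stimuli."""
    base = 0.9 * (0.5 ** np.arange(k))           # per-state responsiveness
    level = (np.arange(1, n_levels + 1)) / n_levels
    return np.clip(np.outer(base, level) * 2.0, 0.0, 1.0)


def simulate_arousal(
    consensus: np.ndarray,
    response_prob: Optional[np.ndarray] = None,
    levels: Sequence[float] = DEFAULT_STIMULUS_LEVELS,
    seed: int = 0,
    interval_min: int = 60,
    fly_id: str = "fly",
    mobile_prob: Optional[np.ndarray] = None,
) -> list[StimulusTrain]:
    """Progressive stimulus trains applied every ``interval_min`` minutes.

    At each train the fly's state is read from ``consensus``; levels are
    applied in ascending order and the fly responds at each with the
    state-conditional probability, the first response ending the train.
    No response at any level leaves the train non-respondent.
    ``mobile_prob`` (per state) optionally marks flies already moving at
    onset, which the analysis excludes.
    """
    consensus = np.asarray(consensus)
    k = int(consensus.max()) + 1
    if response_prob is None:
        response_prob = default_response_probs(k, len(levels))
    response_prob = np.asarray(response_prob, dtype=float)
    if response_prob.shape != (k, len(levels)):
        raise ValueError("response_prob must be (k, n_levels)")
    if np.any(response_prob < 0) or np.any(response_prob > 1):
        raise ValueError("response probabilities must lie in [0, 1]")
    if np.any(np.diff(response_prob, axis=1) < 0):
        raise ValueError("response probability must be non-decreasing in level")
    rng = np.random.default_rng(seed)
    trains = []
    for start in range(0, len(consensus), interval_min):
        state = int(consensus[start])
        mobile = bool(
            mobile_prob is not None and rng.random() < mobile_prob[state]
        )
        responded_at = None
        if not mobile:
            for li in range(len(levels)):
                if rng.random() < response_prob[state, li]:
                    responded_at = li
                    break
        trains.append(StimulusTrain(
            fly_id=fly_id,
            train_start=start,
            levels=tuple(levels),
            responded_at=responded_at,
            mobile_at_onset=mobile,
        ))
    return trains
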