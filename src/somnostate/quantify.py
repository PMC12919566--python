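"""State-duration phenotypes and arousal-threshold analysis.

Converts consensus state sequences into the quantities used downstream:
minutes spent in each state over 24 h and separately by day/night phase
(averaged over a fly's analysis days), and, for validation experiments,
the state-conditional arousal threshold — the weakest vibrational
stimulus (in g) that makes a resting fly move, with non-respondents
assigned the strongest stimulus.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd


from .pipeline import ConsensusResult

logger = logging.getLogger("somnostate")

__all__ = [
    "StateDurations",
    "StimulusTrain",
    "ArousalSummary",
    "DEFAULT_STIMULUS_LEVELS",
    "time_in_state",
    "derive_threshold",
    "arousal_by_state",
    "state_durations_to_frame",
]

PHASES = ("day", "night", "24h")

#: Default vibration ladder, in g: 0.24 to 1.2 in five equal steps.
DEFAULT_STIMULUS_LEVELS = (0.24, 0.48, 0.72, 0.96, 1.20)


@dataclass
class StateDurations:
    """Minutes per state per phase for one fly, averaged over days.

    ``minutes[(state, phase)]`` with phase in {"day", "night", "24h"}.
    The 24 h row always totals 1440 and day + night = 24 h per state.
    """

    fly_id: str
    k: int
    minutes: dict
    n_days: int

    def get(self, state: int, phase: str) -> float:
        return self.minutes[(state, phase)]


@dataclass
class StimulusTrain:
    """One progressive stimulus train applied to one fly.

    ``responded_at`` indexes the first ladder level that elicited
    movement (None = non-respondent); ``mobile_at_onset`` marks flies
    already moving when the train started (excluded from analysis).
    """

    fly_id: str
    train_start: int            # minute index into the consensus sequence
    levels: tuple = DEFAULT_STIMULUS_LEVELS
    responded_at: Optional[int] = None
    mobile_at_onset: bool = False

    def __post_init__(self):
        lv = tuple(self.levels)
        if any(b <= a for a, b in zip(lv, lv[1:])):
            raise ValueError("stimulus levels must be strictly increasing")
        if self.responded_at is not None and not (
            0 <= self.responded_at < len(lv)
        ):
            raise ValueError("responded_at out of range")
        self.levels = lv


@dataclass
class ArousalSummary:
    """Mean arousal threshold (g) per state with SE and sample size."""

    table: pd.DataFrame  # columns: state, mean_g, se_g, n


# ---------------------------------------------------------------------------
# Time in state
# ---------------------------------------------------------------------------

def time_in_state(consensus_days: Sequence[ConsensusResult], k: Optional[int] = None) -> StateDurations:
    """Minutes per state per phase, averaged across a fly's days.

    Every day contributes exactly 1440 minutes, so the 24 h totals are
    conserved under averaging; each consensus day must carry its phase
    labels.
    """
    days = list(consensus_days)
    if not days:
        raise ValueError("no included days; phenotype is missing")
    if k is None:
        k = days[0].k
    per_day = np.zeros((len(days), k, 2))  # day-phase, night-phase
    for d_i, day in enumerate(days):
        if day.phase is None:
            raise ValueError("consensus day lacks phase labels")
        states = day.consensus
        is_day = np.asarray(day.phase) == "day"
        for s in range(k):
            in_s = states == s
            per_day[d_i, s, 0] = np.sum(in_s & is_day)
            per_day[d_i, s, 1] = np.sum(in_s & ~is_day)
    mean = per_day.mean(axis=0)
    minutes = {}
    for s in range(k):
        minutes[(s, "day")] = float(mean[s, 0])
        minutes[(s, "night")] = float(mean[s, 1])
        minutes[(s, "24h")] = float(mean[s, 0] + mean[s, 1])
    return StateDurations(
        fly_id=days[0].fly_id, k=k, minutes=minutes, n_days=len(days)
    )


def state_durations_to_frame(
    durations: Sequence[StateDurations], meta_by_fly: Optional[dict] = None
) -> pd.DataFrame:
    """Long-format table (fly_id, [metadata], state, phase, minutes)."""
    rows = []
    for d in durations:
        meta = meta_by_fly.get(d.fly_id) if meta_by_fly else None
        for s in range(d.k):
            for phase in PHASES:
                row = {"fly_id": d.fly_id, "state": s, "phase": phase,
                       "minutes": d.get(s, phase)}
                if meta is not None:
                    row.update({
                        "genotype": meta.genotype, "sex": meta.sex,
                        "block": meta.block, "replicate": meta.replicate,
                    })
                rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Arousal thresholds
# ---------------------------------------------------------------------------

def derive_threshold(train: StimulusTrain) -> Optional[float]:
    """Arousal threshold of one train, in g.

    Flies already mobile at onset are excluded (returns None).  The
    threshold is the first ladder level that elicited movement;
    non-respondents are assigned the strongest stimulus.
    """
    if train.mobile_at_onset:
        return None
    if train.responded_at is None:
        return float(train.levels[-1])
    return float(train.levels[train.responded_at])


def arousal_by_state(
    trains: Sequence[StimulusTrain],
    consensus: np.ndarray,
    k: Optional[int] = None,
) -> ArousalSummary:
    """Group arousal thresholds by the consensus state at train onset.

    ``consensus`` is the per-minute state sequence covering the
    experiment; trains starting outside its coverage are dropped with a
    log message.  Reports mean, standard error and n per state; states
    with a single observation report SE as missing.
    """
    consensus = np.asarray(consensus)
    if k is None:
        k = int(consensus.max()) + 1
    by_state: dict[int, list[float]] = {s: [] for s in range(k)}
    for train in trains:
        thr = derive_threshold(train)
        if thr is None:
            continue
        if not 0 <= train.train_start < len(consensus):
            logger.info(
                "%s: train at minute %d outside consensus coverage; dropped",
                train.fly_id, train.train_start,
            )
            continue
        state = int(consensus[train.train_start])
        by_state[state].append(thr)
    rows = []
    for s in range(k):
        vals = np.asarray(by_state[s], dtype=float)
        n = len(vals)
        mean = float(vals.mean()) if n else math.nan
        se = float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan
        rows.append({"state": s, "mean_g": mean, "se_g": se, "n": n})
    return ArousalSummary(table=pd.DataFrame(rows))
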