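"""Reading and preparing Drosophila Activity Monitor (DAM2) recordings.

The DAM system records, for each of 32 flies held in glass tubes, the
number of infrared beam crossings per minute.  A DAM2 monitor file is
tab-separated text with one row per minute and 42 fields: record index,
date (``dd Mon yy``), time (``HH:MM:SS``), a status code (1 = valid data),
six auxiliary fields, and the 32 per-channel counts.

This module parses monitor files, binds per-channel fly metadata, assigns
Zeitgeber time and light/dark phase, splits recordings into whole analysis
days of 1440 minutes, and computes the classical 5-minute sleep
definition (any run of 5 or more zero-count minutes).

Minute indexing is 0-based throughout; intervals are half-open
``[start, end)``.  Monitor gaps propagate as missing minutes and
disqualify the containing day from model fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("somnostate")

__all__ = [
    "DamParseError",
    "MonitorTable",
    "FlyMeta",
    "FlySeries",
    "FlyDay",
    "SleepBout",
    "read_dam2",
    "write_dam2",
    "read_metadata",
    "bind_metadata",
    "annotate_phase",
    "split_days",
    "classic_sleep_bouts",
    "fly_days_to_frame",
]

N_CHANNELS = 32
N_FIELDS = 42  # index, date, time, status, 6 auxiliary, 32 counts
MINUTES_PER_DAY = 1440
STATUS_VALID = 1
_DATE_FMT = "%d %b %y %H:%M:%S"


class DamParseError(ValueError):
    """Raised when a monitor file violates the DAM2 dialect."""


@dataclass
class MonitorTable:
    """One parsed DAM2 monitor file.

    ``counts`` is an (n_rows, 32) float array; missing minutes (filled
    monitor gaps) hold NaN and are marked in ``missing``.  Rows whose
    status code differs from the valid-data code are retained but flagged
    via ``status``.
    """

    monitor_id: str
    record_index: np.ndarray
    times: pd.DatetimeIndex
    status: np.ndarray
    counts: np.ndarray
    missing: np.ndarray

    def __len__(self) -> int:
        return len(self.times)

    @property
    def flagged(self) -> np.ndarray:
        """True for rows whose status code is not the valid-data code."""
        return (self.status != STATUS_VALID) & ~self.missing

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.counts, columns=[f"ch{c:02d}" for c in range(1, N_CHANNELS + 1)]
        )
        df.insert(0, "missing", self.missing)
        df.insert(0, "status", self.status)
        df.insert(0, "datetime", self.times)
        df.insert(0, "record_index", self.record_index)
        return df


@dataclass(frozen=True)
class FlyMeta:
    """Metadata for one fly: its monitor channel plus experimental design
    labels (genotype/line, sex, block, replicate, optional treatment)."""

    fly_id: str
    monitor_id: str
    channel: int
    genotype: str
    sex: str
    block: str = ""
    replicate: str = ""
    treatment: Optional[str] = None

    def __post_init__(self):
        if not 1 <= self.channel <= N_CHANNELS:
            raise ValueError(
                f"channel must be in [1, {N_CHANNELS}], got {self.channel}"
            )
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")


@dataclass
class FlySeries:
    """Minute-indexed activity counts for one fly, carrying its metadata.

    ``counts`` is float with NaN for missing minutes.  ``zt_minute`` and
    ``phase`` are filled by :func:`annotate_phase`.
    """

    meta: FlyMeta
    times: pd.DatetimeIndex
    counts: np.ndarray
    zt_minute: Optional[np.ndarray] = None
    phase: Optional[np.ndarray] = None

    @property
    def fly_id(self) -> str:
        return self.meta.fly_id


@dataclass
class FlyDay:
    """One fly x one Zeitgeber day: 1440 per-minute raw counts aligned to
    ZT0, with phase labels; ``normalized`` is filled by the pipeline."""

    fly_id: str
    day_index: int
    raw_counts: np.ndarray
    zt_minute: np.ndarray
    phase: np.ndarray
    normalized: Optional[np.ndarray] = None
    meta: Optional[FlyMeta] = None

    @property
    def has_missing(self) -> bool:
        return bool(np.any(~np.isfinite(self.raw_counts)))


@dataclass(frozen=True)
class SleepBout:
    """A maximal run of zero-count minutes, half-open [start, end)."""

    fly_id: str
    start_minute: int
    end_minute: int

    @property
    def duration_min(self) -> int:
        return self.end_minute - self.start_minute


# ---------------------------------------------------------------------------
# Monitor file I/O
# ---------------------------------------------------------------------------

def read_dam2(path, strict: bool = False) -> MonitorTable:
    """Parse a DAM2 monitor file.

    Rows must carry exactly 42 tab-separated fields with strictly
    increasing one-minute timestamps.  With ``strict`` a timestamp gap
    raises; otherwise gaps are logged and filled with missing-count rows
    so downstream day-splitting stays aligned.
    """
    path = Path(path)
    monitor_id = path.stem
    rec_idx: list[int] = []
    times: list[datetime] = []
    status: list[int] = []
    count_rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != N_FIELDS:
                raise DamParseError(
                    f"{path.name}:{lineno}: expected {N_FIELDS} tab-separated "
                    f"fields, found {len(fields)}"
                )
            try:
                ts = datetime.strptime(f"{fields[1]} {fields[2]}", _DATE_FMT)
            except ValueError as exc:
                raise DamParseError(
                    f"{path.name}:{lineno}: unparseable date/time "
                    f"{fields[1]!r} {fields[2]!r}"
                ) from exc
            try:
                idx = int(fields[0])
                stat = int(fields[3])
                row = [int(v) for v in fields[10:]]
            except ValueError as exc:
                raise DamParseError(
                    f"{path.name}:{lineno}: non-integer field"
                ) from exc
            if any(v < 0 for v in row):
                raise DamParseError(f"{path.name}:{lineno}: negative count")
            rec_idx.append(idx)
            times.append(ts)
            status.append(stat)
            count_rows.append(row)
    if not times:
        raise DamParseError(f"{path.name}: empty monitor file")

    # enforce / repair the one-minute grid
    out_idx = [rec_idx[0]]
    out_times = [times[0]]
    out_status = [status[0]]
    out_counts = [count_rows[0]]
    out_missing = [False]
    one_min = timedelta(minutes=1)
    for i in range(1, len(times)):
        gap = times[i] - out_times[-1]
        if gap <= timedelta(0):
            raise DamParseError(
                f"{path.name}: timestamps not strictly increasing at "
                f"{times[i]:%Y-%m-%d %H:%M}"
            )
        if gap > one_min:
            n_fill = int(gap / one_min) - 1
            if strict:
                raise DamParseError(
                    f"{path.name}: {n_fill}-minute gap before "
                    f"{times[i]:%Y-%m-%d %H:%M} (strict mode)"
                )
            logger.warning(
                "%s: filling %d missing minute(s) before %s",
                path.name, n_fill, times[i],
            )
            for _ in range(n_fill):
                out_idx.append(-1)
                out_times.append(out_times[-1] + one_min)
                out_status.append(-1)
                out_counts.append([np.nan] * N_CHANNELS)
                out_missing.append(True)
        out_idx.append(rec_idx[i])
        out_times.append(times[i])
        out_status.append(status[i])
        out_counts.append(count_rows[i])
        out_missing.append(False)

    return MonitorTable(
        monitor_id=monitor_id,
        record_index=np.asarray(out_idx, dtype=int),
        times=pd.DatetimeIndex(out_times),
        status=np.asarray(out_status, dtype=int),
        counts=np.asarray(out_counts, dtype=float),
        missing=np.asarray(out_missing, dtype=bool),
    )


def write_dam2(table: MonitorTable, path) -> Path:
    """Write a MonitorTable back to the DAM2 dialect (auxiliary fields
    zeroed).  Missing-filled rows are not representable and are skipped."""
    path = Path(path)
    with open(path, "w") as fh:
        for i in range(len(table)):
            if table.missing[i]:
                continue
            ts = table.times[i].to_pydatetime()
            fields = [
                str(int(table.record_index[i])),
                ts.strftime("%d %b %y"),
                ts.strftime("%H:%M:%S"),
                str(int(table.status[i])),
            ] + ["0"] * 6 + [str(int(v)) for v in table.counts[i]]
            fh.write("\t".join(fields) + "\n")
    return path


# ---------------------------------------------------------------------------
# Metadata binding and phase annotation
# ---------------------------------------------------------------------------

def read_metadata(path) -> list[FlyMeta]:
    """Read a metadata CSV with header
    fly_id,monitor_id,channel,genotype,sex,block,replicate[,treatment]."""
    df = pd.read_csv(path, dtype=str)
    required = {"fly_id", "monitor_id", "channel", "genotype", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata CSV missing columns: {sorted(missing)}")
    metas = []
    for rec in df.to_dict("records"):
        treatment = rec.get("treatment")
        if treatment is not None and pd.isna(treatment):
            treatment = None
        metas.append(FlyMeta(
            fly_id=rec["fly_id"],
            monitor_id=rec["monitor_id"],
            channel=int(rec["channel"]),
            genotype=rec["genotype"],
            sex=rec["sex"],
            block=rec.get("block", "") or "",
            replicate=rec.get("replicate", "") or "",
            treatment=treatment,
        ))
    return metas


def bind_metadata(
    monitor: MonitorTable, meta: Sequence[FlyMeta]
) -> list[FlySeries]:
    """Attach fly metadata to monitor channels, one minute series per fly.

    Channels without a metadata row are dropped (logged); metadata naming
    a channel outside the monitor or duplicating a (monitor, channel)
    pair is an error.
    """
    seen: set[tuple[str, int]] = set()
    series = []
    relevant = [m for m in meta if m.monitor_id == monitor.monitor_id]
    for m in relevant:
        key = (m.monitor_id, m.channel)
        if key in seen:
            raise ValueError(f"duplicate metadata for monitor/channel {key}")
        seen.add(key)
        series.append(FlySeries(
            meta=m,
            times=monitor.times,
            counts=monitor.counts[:, m.channel - 1].copy(),
        ))
    unused = N_CHANNELS - len(relevant)
    if unused:
        logger.info(
            "%s: %d channel(s) without metadata dropped",
            monitor.monitor_id, unused,
        )
    return series


def annotate_phase(
    series: FlySeries,
    lights_on: str = "08:00",
    photoperiod_hours: float = 12.0,
) -> FlySeries:
    """Assign Zeitgeber time and light/dark phase to every minute.

    ZT0 is the most recent lights-on; a minute is "day" iff its ZT is
    inside the photoperiod.
    """
    if not 0.0 < photoperiod_hours < 24.0:
        raise ValueError("photoperiod_hours must be in (0, 24)")
    hh, mm = (int(v) for v in lights_on.split(":"))
    on_min = hh * 60 + mm
    minutes_of_day = series.times.hour * 60 + series.times.minute
    zt = (np.asarray(minutes_of_day) - on_min) % MINUTES_PER_DAY
    phase = np.where(zt < photoperiod_hours * 60, "day", "night")
    return replace(series, zt_minute=zt.astype(int), phase=phase)


def split_days(
    series: FlySeries, drop_first: bool = True, n_days: int = 4
) -> list[FlyDay]:
    """Cut an annotated series into whole ZT-aligned days of 1440 minutes.

    Partial leading/trailing days are discarded; with ``drop_first`` the
    first full day (acclimation) is excluded and exactly ``n_days``
    subsequent days are returned.
    """
    if series.zt_minute is None:
        raise ValueError("series must be phase-annotated before splitting")
    zt = series.zt_minute
    starts = np.flatnonzero(zt == 0)
    full_starts = [s for s in starts if s + MINUTES_PER_DAY <= len(zt)]
    needed = n_days + int(drop_first)
    if len(full_starts) < needed:
        raise ValueError(
            f"{series.fly_id}: need {needed} full days, "
            f"only {len(full_starts)} available"
        )
    chosen = full_starts[int(drop_first): int(drop_first) + n_days]
    days = []
    for j, s in enumerate(chosen):
        sl = slice(s, s + MINUTES_PER_DAY)
        day = FlyDay(
            fly_id=series.fly_id,
            day_index=int(drop_first) + j + 1,
            raw_counts=series.counts[sl].copy(),
            zt_minute=zt[sl].copy(),
            phase=series.phase[sl].copy(),
            meta=series.meta,
        )
        if day.has_missing:
            logger.warning(
                "%s day %d contains missing minutes; excluded from fitting",
                day.fly_id, day.day_index,
            )
        days.append(day)
    return days


# ---------------------------------------------------------------------------
# Classical sleep definition
# ---------------------------------------------------------------------------

def classic_sleep_bouts(
    day: FlyDay, min_quiescent: int = 5
) -> tuple[list[SleepBout], int]:
    """Sleep by the classical definition: any maximal run of zero-count
    minutes of length >= ``min_quiescent`` is a sleep bout.  Returns the
    bouts and the total sleep minutes.  Missing minutes break runs."""
    if min_quiescent < 1:
        raise ValueError("min_quiescent must be >= 1")
    x = day.raw_counts
    is_zero = np.isfinite(x) & (x == 0)
    bouts = []
    total = 0
    start = None
    for i in range(len(x) + 1):
        if i < len(x) and is_zero[i]:
            if start is None:
                start = i
        else:
            if start is not None and i - start >= min_quiescent:
                bouts.append(SleepBout(day.fly_id, start, i))
                total += i - start
            start = None
    return bouts, total


def fly_days_to_frame(days: Sequence[FlyDay]) -> pd.DataFrame:
    """Tidy per-fly per-minute table (fly_id, day_index, zt_minute, phase,
    count) for export."""
    frames = []
    for d in days:
        frames.append(pd.DataFrame({
            "fly_id": d.fly_id,
            "day_index": d.day_index,
            "zt_minute": d.zt_minute,
            "phase": d.phase,
            "count": d.raw_counts,
        }))
    return pd.concat(frames, ignore_index=True)
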