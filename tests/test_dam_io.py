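"""DAM2 parsing, metadata binding, phase annotation, day splitting,
classical sleep bouts."""

import numpy as np
import pandas as pd
import pytest

from somnostate import dam_io, synthetic
from somnostate.dam_io import (
    DamParseError,
    FlyDay,
    FlyMeta,
    annotate_phase,
    bind_metadata,
    classic_sleep_bouts,
    read_dam2,
    split_days,
    write_dam2,
)


def _dam_line(idx, date, time, counts, status=1):
    fields = [str(idx), date, time, str(status)] + ["0"] * 6
    fields += [str(c) for c in counts]
    return "\t".join(fields)


def _write(tmp_path, lines, name="Monitor9.txt"):
    p = tmp_path / name
    p.write_text("\n".join(lines) + "\n")
    return p


@pytest.fixture
def three_lines(tmp_path):
    counts = [2] + [0] * 31
    lines = [
        _dam_line(i + 1, "01 Jan 24", f"08:0{i}:00", counts)
        for i in range(3)
    ]
    return _write(tmp_path, lines)


def test_read_basic_fixture(three_lines):
    table = read_dam2(three_lines)
    assert len(table) == 3
    assert np.all(table.counts[:, 0] == 2)
    assert np.all(table.counts[:, 1:] == 0)
    assert table.monitor_id == "Monitor9"


def test_wrong_field_count_names_line(tmp_path):
    good = _dam_line(1, "01 Jan 24", "08:00:00", [0] * 32)
    bad = good.rsplit("\t", 1)[0]  # 41 fields
    path = _write(tmp_path, [good, bad])
    with pytest.raises(DamParseError, match=":2"):
        read_dam2(path)


def test_bad_timestamp_is_parse_error(tmp_path):
    path = _write(tmp_path, [_dam_line(1, "01 Foo 24", "08:00:00", [0] * 32)])
    with pytest.raises(DamParseError, match="date/time"):
        read_dam2(path)


def test_empty_file_rejected(tmp_path):
    path = _write(tmp_path, [""])
    with pytest.raises(DamParseError, match="empty"):
        read_dam2(path)


def test_gap_filled_with_missing_row(tmp_path):
    lines = [
        _dam_line(1, "01 Jan 24", "08:00:00", [1] * 32),
        _dam_line(2, "01 Jan 24", "08:02:00", [1] * 32),  # 2-minute jump
    ]
    table = read_dam2(_write(tmp_path, lines))
    assert len(table) == 3
    assert table.missing.tolist() == [False, True, False]
    assert np.all(np.isnan(table.counts[1]))


def test_gap_raises_in_strict_mode(tmp_path):
    lines = [
        _dam_line(1, "01 Jan 24", "08:00:00", [1] * 32),
        _dam_line(2, "01 Jan 24", "08:02:00", [1] * 32),
    ]
    with pytest.raises(DamParseError, match="gap"):
        read_dam2(_write(tmp_path, lines), strict=True)


def test_nonvalid_status_rows_flagged(tmp_path):
    lines = [
        _dam_line(1, "01 Jan 24", "08:00:00", [1] * 32, status=1),
        _dam_line(2, "01 Jan 24", "08:01:00", [1] * 32, status=51),
    ]
    table = read_dam2(_write(tmp_path, lines))
    assert table.flagged.tolist() == [False, True]


def test_round_trip_preserves_counts_and_times(tmp_path):
    table, _, _ = synthetic.simulate_monitor(n_flies=4, days=1, seed=5)
    path = write_dam2(table, tmp_path / "Monitor1.txt")
    back = read_dam2(path)
    assert np.array_equal(back.counts, table.counts)
    assert back.times.equals(table.times)
    assert np.array_equal(back.record_index, table.record_index)


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------

def _meta(ch, fly=None):
    return FlyMeta(fly_id=fly or f"f{ch}", monitor_id="Monitor9", channel=ch,
                   genotype="L1", sex="F")


def test_bind_two_rows(three_lines):
    table = read_dam2(three_lines)
    series = bind_metadata(table, [_meta(1), _meta(2)])
    assert [s.fly_id for s in series] == ["f1", "f2"]
    assert series[0].counts.tolist() == [2, 2, 2]
    assert series[1].counts.tolist() == [0, 0, 0]


def test_channel_out_of_range_rejected():
    with pytest.raises(ValueError, match="channel"):
        FlyMeta(fly_id="x", monitor_id="M", channel=33, genotype="g", sex="F")


def test_duplicate_channel_rejected(three_lines):
    table = read_dam2(three_lines)
    with pytest.raises(ValueError, match="duplicate"):
        bind_metadata(table, [_meta(1), _meta(1, fly="other")])


def test_metadata_csv_round_trip(tmp_path):
    df = pd.DataFrame([
        {"fly_id": "a", "monitor_id": "M1", "channel": 1, "genotype": "L1",
         "sex": "F", "block": "b1", "replicate": "r1"},
        {"fly_id": "b", "monitor_id": "M1", "channel": 2, "genotype": "L2",
         "sex": "M", "block": "b1", "replicate": "r2"},
    ])
    path = tmp_path / "meta.csv"
    df.to_csv(path, index=False)
    metas = dam_io.read_metadata(path)
    assert [m.fly_id for m in metas] == ["a", "b"]
    assert metas[1].sex == "M"


# ---------------------------------------------------------------------------
# Phase annotation and day splitting
# ---------------------------------------------------------------------------

def _series_at(times):
    meta = _meta(1)
    idx = pd.DatetimeIndex(times)
    return dam_io.FlySeries(meta=meta, times=idx,
                            counts=np.zeros(len(idx)))


@pytest.mark.parametrize("clock,zt,phase", [
    ("2024-01-01 08:00", 0, "day"),
    ("2024-01-01 20:00", 720, "night"),
    ("2024-01-01 07:59", 1439, "night"),
])
def test_zeitgeber_annotation(clock, zt, phase):
    s = annotate_phase(_series_at([clock]), lights_on="08:00")
    assert s.zt_minute[0] == zt
    assert s.phase[0] == phase


def _long_series(n_days, start="2024-01-01 08:00"):
    times = pd.date_range(start, periods=n_days * 1440, freq="min")
    s = _series_at(times)
    s.counts = np.arange(len(times), dtype=float)
    return annotate_phase(s, lights_on="08:00")


def test_split_days_default_drops_first():
    days = split_days(_long_series(5))
    assert [d.day_index for d in days] == [2, 3, 4, 5]
    assert all(len(d.raw_counts) == 1440 for d in days)
    # contiguous, non-overlapping coverage
    cat = np.concatenate([d.raw_counts for d in days])
    assert np.array_equal(cat, np.arange(1440, 5 * 1440, dtype=float))


def test_split_days_insufficient_data():
    with pytest.raises(ValueError, match="5 full days"):
        split_days(_long_series(3))


def test_split_days_keep_first():
    days = split_days(_long_series(5), drop_first=False, n_days=5)
    assert [d.day_index for d in days] == [1, 2, 3, 4, 5]


def test_split_days_discards_partial_leading_day():
    # recording starts mid-photoperiod: the partial day must be skipped
    s = _long_series(6, start="2024-01-01 13:30")
    days = split_days(s)
    assert all(d.zt_minute[0] == 0 for d in days)


# ---------------------------------------------------------------------------
# Classical sleep
# ---------------------------------------------------------------------------

def _day_from_counts(counts):
    counts = np.asarray(counts, dtype=float)
    zt = np.arange(1440)
    return FlyDay(fly_id="f", day_index=1, raw_counts=counts,
                  zt_minute=zt, phase=np.where(zt < 720, "day", "night"))


def test_five_zero_minutes_is_one_bout():
    counts = np.ones(1440)
    counts[100:105] = 0
    bouts, total = classic_sleep_bouts(_day_from_counts(counts))
    assert len(bouts) == 1 and total == 5
    assert (bouts[0].start_minute, bouts[0].end_minute) == (100, 105)


def test_four_zero_minutes_below_threshold():
    counts = np.ones(1440)
    counts[100:104] = 0
    bouts, total = classic_sleep_bouts(_day_from_counts(counts))
    assert bouts == [] and total == 0


def test_all_zero_day_single_bout():
    bouts, total = classic_sleep_bouts(_day_from_counts(np.zeros(1440)))
    assert len(bouts) == 1 and total == 1440
    assert bouts[0].duration_min == 1440


def test_bout_total_matches_scan_oracle(rng):
    # total sleep equals count of zero-minutes in runs >= threshold
    for _ in range(20):
        counts = (rng.random(1440) < 0.6).astype(float)  # many zeros
        day = _day_from_counts(counts)
        _, total = classic_sleep_bouts(day, min_quiescent=5)
        run = 0
        expect = 0
        for v in np.append(counts, 1.0):
            if v == 0:
                run += 1
            else:
                if run >= 5:
                    expect += run
                run = 0
        assert total == expect
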