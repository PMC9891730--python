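import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from frusc.behavior import (
    SLEEP_MIN_RUN,
    chisq_periodogram,
    detect_sleep,
    filter_dead,
    group_summaries,
    read_activity_csv,
    read_monitor_file,
)
from frusc.simulate import ActivityTrace, SimActivitySpec, simulate_activity, write_activity_csv


def pad_day(prefix, fill=1):
    """Build a single-day (1440 min) trace starting with ``prefix``."""
    counts = np.full(1440, fill, dtype=int)
    counts[: len(prefix)] = prefix
    return counts


def brute_force_sleep_minutes(counts):
    """Oracle: a minute is asleep iff it sits inside some window of
    >= SLEEP_MIN_RUN consecutive zeros; scan every window."""
    n = len(counts)
    asleep = np.zeros(n, dtype=bool)
    for start in range(n - SLEEP_MIN_RUN + 1):
        window = counts[start : start + SLEEP_MIN_RUN]
        if all(v == 0 for v in window):
            asleep[start : start + SLEEP_MIN_RUN] = True
    return int(asleep.sum())


class TestFilterDead:
    def test_day_below_50_removed(self):
        counts = pad_day([], fill=0)
        counts[:49] = 1  # day total 49
        kept, removed = filter_dead([ActivityTrace("f1", counts)])
        assert removed == ["f1"]

    def test_exactly_50_kept(self):
        counts = pad_day([], fill=0)
        counts[:50] = 1
        kept, removed = filter_dead([ActivityTrace("f1", counts)])
        assert kept and not removed

    def test_all_active_none_removed(self):
        traces = [ActivityTrace(f"f{i}", pad_day([], fill=1)) for i in range(3)]
        kept, removed = filter_dead(traces)
        assert len(kept) == 3 and not removed


class TestDetectSleep:
    def test_five_minute_bout(self):
        s = detect_sleep(ActivityTrace("x", pad_day([1, 0, 0, 0, 0, 0, 1])))
        assert s.bout_count == 1
        assert s.total_sleep_min == 5

    def test_four_minutes_no_sleep(self):
        s = detect_sleep(ActivityTrace("x", pad_day([1, 0, 0, 0, 0, 1])))
        assert s.total_sleep_min == 0

    def test_all_zero_day_single_bout(self):
        s = detect_sleep(ActivityTrace("x", np.zeros(1440, dtype=int)))
        assert s.bout_count == 1
        assert s.total_sleep_min == 1440
        assert s.mean_bout_min == 1440

    def test_day_night_split(self):
        counts = np.ones(1440, dtype=int)
        counts[470:490] = 0  # 20-min bout spanning lights-on at 480
        s = detect_sleep(ActivityTrace("x", counts, lights_on=480, lights_off=1200))
        assert s.total_sleep_min == 20
        assert s.night_sleep_min == 10
        assert s.day_sleep_min == 10

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.integers(0, 1), min_size=0, max_size=60))
    def test_matches_bruteforce_window_scan(self, prefix):
        counts = pad_day(prefix)
        s = detect_sleep(ActivityTrace("x", counts))
        assert s.total_sleep_min == brute_force_sleep_minutes(counts)
        assert s.day_sleep_min + s.night_sleep_min == s.total_sleep_min
        if s.bout_count:
            assert s.mean_bout_min >= SLEEP_MIN_RUN


class TestPeriodogram:
    def test_square_wave_peak_exact(self):
        t = np.arange(10 * 1440)
        counts = (np.sin(2 * np.pi * t / (24 * 60)) >= 0).astype(int) * 5
        pg = chisq_periodogram(ActivityTrace("sq", counts))
        assert pg.peak_period_h == 24.0
        assert pg.rhythmic

    def test_constant_activity_arrhythmic(self):
        pg = chisq_periodogram(ActivityTrace("c", np.full(10 * 1440, 3)))
        assert not pg.rhythmic
        assert pg.peak_period_h is None

    def test_scale_invariance(self):
        trs = simulate_activity(SimActivitySpec(n_flies=1, n_days=10, period_h=25.0, seed=3))
        pg1 = chisq_periodogram(trs[0])
        pg2 = chisq_periodogram(trs[0].counts * 7)
        assert pg1.peak_period_h == pg2.peak_period_h

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError, match="minutes"):
            chisq_periodogram(ActivityTrace("s", np.ones(1440, dtype=int)))

    def test_planted_period_recovery(self):
        hits = 0
        for seed in range(20):
            trs = simulate_activity(
                SimActivitySpec(n_flies=1, n_days=10, period_h=22.8, amplitude=1.0,
                                baseline_rate=1.0, seed=seed)
            )
            pg = chisq_periodogram(trs[0])
            hits += pg.peak_period_h is not None and abs(pg.peak_period_h - 22.8) <= 0.2
        assert hits >= 19

    def test_zero_amplitude_rarely_significant(self):
        hits = 0
        for seed in range(20):
            trs = simulate_activity(
                SimActivitySpec(n_flies=1, n_days=10, amplitude=0.0, baseline_rate=1.0, seed=seed)
            )
            hits += chisq_periodogram(trs[0]).rhythmic
        assert hits <= 1


class TestGroupSummaries:
    def test_period_mean(self):
        df = pd.DataFrame(
            [{"genotype": "g", "sex": "m", "period_h": 22.8, "rhythmic": True},
             {"genotype": "g", "sex": "m", "period_h": 23.0, "rhythmic": True}]
        )
        out = group_summaries(df, ["genotype", "sex"])
        assert out["period_h_mean"].iloc[0] == pytest.approx(22.9)

    def test_arrhythmic_excluded_and_counted(self):
        df = pd.DataFrame(
            [{"genotype": "g", "period_h": 24.0, "rhythmic": True},
             {"genotype": "g", "period_h": 24.2, "rhythmic": True},
             {"genotype": "g", "period_h": np.nan, "rhythmic": False}]
        )
        out = group_summaries(df, ["genotype"])
        assert out["n_arrhythmic_excluded"].iloc[0] == 1
        assert out["period_h_mean"].iloc[0] == pytest.approx(24.1)

    def test_single_group(self):
        df = pd.DataFrame([{"genotype": "g", "total_sleep_min": 600}])
        out = group_summaries(df, ["genotype"])
        assert len(out) == 1
        assert out["total_sleep_min_mean"].iloc[0] == 600


class TestIO:
    def test_activity_csv_roundtrip(self, tmp_path):
        traces = simulate_activity(SimActivitySpec(n_flies=3, n_days=2, seed=0))
        write_activity_csv(traces, tmp_path / "act.csv", tmp_path / "sched.json")
        back = read_activity_csv(tmp_path / "act.csv", tmp_path / "sched.json")
        assert len(back) == 3
        assert all(np.array_equal(a.counts, b.counts) for a, b in zip(sorted(traces, key=lambda t: t.fly_id), back))
        assert back[0].lights_on == 480

    def test_monitor_file_reader(self, tmp_path):
        rng = np.random.default_rng(0)
        lines = []
        for minute in range(1440):
            counts = rng.integers(0, 3, size=32)
            lines.append("\t".join(["1", "01 Jan 20", "00:00:00", "1"] + [str(c) for c in counts]))
        lines.insert(0, "malformed header line")
        (tmp_path / "monitor.txt").write_text("\n".join(lines))
        traces = read_monitor_file(tmp_path / "monitor.txt")
        assert len(traces) == 32
        assert traces[0].counts.size == 1440
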