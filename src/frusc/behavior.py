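"""Locomotor-activity analysis for Drosophila activity monitors (DAM):
dead-fly filtering, sleep detection, and chi-square periodogram
rhythmicity analysis on per-fly 1-minute beam-cross traces.

Sleep follows the standard fly convention: any run of at least 5
consecutive minutes with zero beam crossings is a sleep bout.  Circadian
period is estimated with the Sokolove-Bushell chi-square periodogram: for
each candidate period P (minutes) the trace is folded into P one-minute
bins over K complete cycles (partial final cycle dropped) and

    Qp = K * sum_h (M_h - M)^2 / s^2

where M_h are bin means, M the grand mean, and s^2 the variance of the
folded samples; under the null Qp ~ chi-square with P - 1 degrees of
freedom.  A fly is rhythmic when max Qp / Qp_crit >= 1 over the tested
grid, and its period is the grid point maximizing Qp among significant
ones.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .simulate import ActivityTrace

__all__ = [
    "SleepSummary",
    "PeriodogramResult",
    "read_activity_csv",
    "read_monitor_file",
    "filter_dead",
    "detect_sleep",
    "chisq_periodogram",
    "group_summaries",
]

SLEEP_MIN_RUN = 5


def read_activity_csv(csv_path: str | Path, schedule_path: str | Path | None = None) -> list[ActivityTrace]:
    """Read long-form activity CSV (fly_id, minute_index, counts) plus an
    optional schedule JSON with lights_on / lights_off minutes of day."""
    df = pd.read_csv(csv_path)
    schedule = {"lights_on": 480, "lights_off": 1200}
    if schedule_path is not None:
        schedule.update(json.loads(Path(schedule_path).read_text()))
    traces = []
    for fly_id, grp in df.groupby("fly_id", sort=True):
        grp = grp.sort_values("minute_index")
        traces.append(
            ActivityTrace(
                fly_id=str(fly_id),
                counts=grp["counts"].to_numpy(),
                lights_on=schedule["lights_on"],
                lights_off=schedule["lights_off"],
            )
        )
    return traces


def read_monitor_file(
    path: str | Path,
    lights_on: int = 480,
    lights_off: int = 1200,
    n_channels: int = 32,
) -> list[ActivityTrace]:
    """Permissive reader for Trikinetics-style monitor text: tab-separated
    rows, trailing ``n_channels`` integer columns = per-channel counts of
    one minute.  Rows that do not end in ``n_channels`` integers are
    skipped.  Incomplete trailing days are dropped."""
    rows = []
    for line in Path(path).read_text().splitlines():
        parts = line.rstrip("\n").split("\t")
        if len(parts) < n_channels:
            continue
        tail = parts[-n_channels:]
        try:
            rows.append([int(v) for v in tail])
        except ValueError:
            continue
    data = np.asarray(rows, dtype=np.int64)
    if data.size == 0:
        raise ValueError(f"no channel-count rows parsed from {path}")
    n_full = (data.shape[0] // 1440) * 1440
    if n_full == 0:
        raise ValueError("monitor file contains less than one full day of data")
    data = data[:n_full]
    return [
        ActivityTrace(fly_id=f"ch{c + 1:02d}", counts=data[:, c], lights_on=lights_on, lights_off=lights_off)
        for c in range(n_channels)
    ]


def filter_dead(traces: list[ActivityTrace], min_daily: int = 50) -> tuple[list[ActivityTrace], list[str]]:
    """Remove flies with any full day below ``min_daily`` beam crossings
    (strict <); returns (kept traces, removed fly ids)."""
    kept, removed = [], []
    for tr in traces:
        daily = tr.counts.reshape(tr.n_days, 1440).sum(axis=1)
        (removed if (daily < min_daily).any() else kept).append(tr)
    return kept, [tr.fly_id for tr in removed]


@dataclass
class SleepSummary:
    fly_id: str
    total_sleep_min: int
    day_sleep_min: int
    night_sleep_min: int
    bout_count: int
    mean_bout_min: float


def _zero_runs(counts: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of zeros as (start, length)."""
    runs = []
    start = None
    for i, v in enumerate(counts):
        if v == 0:
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i - start))
            start = None
    if start is not None:
        runs.append((start, len(counts) - start))
    return runs


def detect_sleep(trace: ActivityTrace) -> SleepSummary:
    """Sleep bouts are maximal runs of >= 5 consecutive zero-count
    minutes.  Day/night minutes are split by the light schedule; a bout
    spanning a transition contributes to both sides."""
    runs = [(s, l) for s, l in _zero_runs(trace.counts) if l >= SLEEP_MIN_RUN]
    minute_of_day = np.arange(trace.counts.size) % 1440
    on, off = trace.lights_on, trace.lights_off
    if on <= off:
        is_day = (minute_of_day >= on) & (minute_of_day < off)
    else:  # lights span midnight
        is_day = (minute_of_day >= on) | (minute_of_day < off)
    asleep = np.zeros(trace.counts.size, dtype=bool)
    for s, l in runs:
        asleep[s : s + l] = True
    total = int(asleep.sum())
    day = int((asleep & is_day).sum())
    return SleepSummary(
        fly_id=trace.fly_id,
        total_sleep_min=total,
        day_sleep_min=day,
        night_sleep_min=total - day,
        bout_count=len(runs),
        mean_bout_min=total / len(runs) if runs else 0.0,
    )


@dataclass
class PeriodogramResult:
    fly_id: str
    periods_h: np.ndarray
    Qp: np.ndarray
    Qp_sig: np.ndarray
    peak_period_h: float | None
    rhythmicity_ratio: float
    rhythmic: bool


def chisq_periodogram(
    trace: ActivityTrace | np.ndarray,
    range_h: tuple[float, float] = (18.0, 30.0),
    step_h: float = 0.2,
    alpha: float = 0.05,
    correct: str = "bonferroni",
    fly_id: str = "",
) -> PeriodogramResult:
    """Sokolove-Bushell chi-square periodogram over a period grid.

    Candidate periods run from ``range_h[0]`` to ``range_h[1]`` in
    ``step_h`` steps; each is rounded to whole minutes for binning.  The
    trace must cover at least two full cycles of the longest test period.

    Because the grid tests many periods, the significance line uses a
    Bonferroni-corrected alpha by default (``correct="none"`` restores
    the per-period threshold); without correction an arrhythmic fly
    crosses the line somewhere on the grid far more often than alpha.
    """
    counts = trace.counts if isinstance(trace, ActivityTrace) else np.asarray(trace, dtype=float)
    if isinstance(trace, ActivityTrace) and not fly_id:
        fly_id = trace.fly_id
    lo, hi = range_h
    n_steps = int(round((hi - lo) / step_h))
    periods_h = lo + step_h * np.arange(n_steps + 1)
    min_len = 2 * int(round(hi * 60))
    if counts.size < min_len:
        raise ValueError(f"trace too short for periodogram: need >= {min_len} minutes, got {counts.size}")

    if correct == "bonferroni":
        alpha_eff = alpha / periods_h.size
    elif correct == "none":
        alpha_eff = alpha
    else:
        raise ValueError(f"correct must be 'bonferroni' or 'none', got '{correct}'")

    x = counts.astype(float)
    Qp = np.zeros_like(periods_h)
    Qp_sig = np.zeros_like(periods_h)
    for i, ph in enumerate(periods_h):
        P = int(round(ph * 60))
        K = counts.size // P
        folded = x[: K * P].reshape(K, P)
        bin_means = folded.mean(axis=0)
        grand = folded.mean()
        s2 = folded.var()
        Qp[i] = 0.0 if s2 == 0 else K * np.sum((bin_means - grand) ** 2) / s2
        Qp_sig[i] = chi2.ppf(1.0 - alpha_eff, df=P - 1)

    ratios = Qp / Qp_sig
    best = float(ratios.max())
    sig = np.flatnonzero(Qp >= Qp_sig)
    if sig.size:
        peak = float(periods_h[sig[np.argmax(Qp[sig])]])
    else:
        peak = None
    return PeriodogramResult(
        fly_id=fly_id,
        periods_h=periods_h,
        Qp=Qp,
        Qp_sig=Qp_sig,
        peak_period_h=peak,
        rhythmicity_ratio=best,
        rhythmic=best >= 1.0,
    )


def group_summaries(per_fly: pd.DataFrame, group_keys: list[str]) -> pd.DataFrame:
    """Group-level means / medians / SDs of activity, sleep, and period.

    ``per_fly`` needs one row per fly with the grouping columns plus any
    of: ``total_activity``, ``total_sleep_min``, ``day_sleep_min``,
    ``night_sleep_min``, ``period_h``, ``rhythmic``.  Arrhythmic flies are
    excluded from period statistics; the exclusion count is reported per
    group.  Empty groups are omitted (pandas drops them) with a warning
    when a grouping level is entirely absent.
    """
    metrics = [
        c for c in ("total_activity", "total_sleep_min", "day_sleep_min", "night_sleep_min")
        if c in per_fly.columns
    ]
    rows = []
    for keys, grp in per_fly.groupby(group_keys, sort=True, observed=True):
        if grp.empty:
            warnings.warn(f"empty group {keys}; omitted")
            continue
        row = dict(zip(group_keys, keys if isinstance(keys, tuple) else (keys,)))
        row["n_flies"] = len(grp)
        for m in metrics:
            row[f"{m}_mean"] = grp[m].mean()
            row[f"{m}_median"] = grp[m].median()
            row[f"{m}_sd"] = grp[m].std(ddof=1) if len(grp) > 1 else 0.0
        if "period_h" in grp.columns:
            rhythmic = grp[grp["rhythmic"]] if "rhythmic" in grp.columns else grp
            rhythmic = rhythmic.dropna(subset=["period_h"])
            row["n_arrhythmic_excluded"] = len(grp) - len(rhythmic)
            row["period_h_mean"] = rhythmic["period_h"].mean() if len(rhythmic) else np.nan
            row["period_h_sd"] = rhythmic["period_h"].std(ddof=1) if len(rhythmic) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
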