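"""Blood-pressure variability indices.

Short-term (within 24 h): average real variability (ARV), SD of the 96
15-min epoch means, duration-weighted day/night SD, and the spread
between the top and bottom quartile subsets of a day's readings.
Long-term (day-to-day): SD and coefficient of variation of the three
daily means of a weekly recording window — the telemetric analogue of
clinical visit-to-visit variability.

All SDs use the n-1 denominator.  The CV is computed per rat (SD of that
rat's daily means over their mean) before any group averaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .telemetry import DailySummary, TelemetryEpochSeries, daily_means

#: A day is usable for 24-h indices when at least this many of its 96
#: epochs are present.
MIN_EPOCHS_PER_DAY = 90


def arv(values: np.ndarray, intervals: np.ndarray | None = None) -> float:
    """Average real variability: time-weighted mean absolute successive
    difference between validated consecutive readings.

    ``ARV = sum_k w_k |BP_k - BP_{k-1}| / sum_k w_k`` where ``w_k`` is the
    time interval separating readings ``k-1`` and ``k``.  With uniform
    intervals this is the plain mean absolute successive difference.

    Readings that are NaN (missing epochs) break the chain: no difference
    is computed across a gap.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("ARV needs at least two readings")
    if intervals is None:
        w = np.ones(v.size - 1)
    else:
        w = np.asarray(intervals, dtype=float)
        if w.size != v.size - 1:
            raise ValueError("need one interval per consecutive pair")
        if np.any(w <= 0):
            raise ValueError("intervals must be positive")
    diffs = np.abs(np.diff(v))
    ok = ~np.isnan(diffs)
    if not np.any(ok):
        raise ValueError("no consecutive pair of valid readings")
    return float(np.sum(w[ok] * diffs[ok]) / np.sum(w[ok]))


def sd_24h(day_epochs: np.ndarray, strict: bool = True,
           min_epochs: int = MIN_EPOCHS_PER_DAY) -> float:
    """Sample SD of one day's 15-min epoch means (96 when complete)."""
    v = np.asarray(day_epochs, dtype=float)
    valid = v[~np.isnan(v)]
    if strict and valid.size < min_epochs:
        raise ValueError(
            f"incomplete day: {valid.size} epochs (< {min_epochs})")
    if valid.size < 2:
        raise ValueError("need at least two epochs")
    return float(np.std(valid, ddof=1))


def weighted_sd_24h(day_values: np.ndarray, night_values: np.ndarray,
                    day_hours: float = 12.0, night_hours: float = 12.0) -> float:
    """Mean of daytime and nighttime SDs weighted by period duration.

    With a 12/12 light-dark cycle this reduces to the plain mean of the
    two SDs (and carries no information beyond them).
    """
    d = np.asarray(day_values, dtype=float)
    n = np.asarray(night_values, dtype=float)
    d, n = d[~np.isnan(d)], n[~np.isnan(n)]
    if d.size < 2 or n.size < 2:
        raise ValueError("each period needs at least two epochs")
    sd_d, sd_n = np.std(d, ddof=1), np.std(n, ddof=1)
    return float((sd_d * day_hours + sd_n * night_hours)
                 / (day_hours + night_hours))


def day_to_day_sd(daily: list[DailySummary] | np.ndarray,
                  variable: str = "sbp") -> float:
    """SD of the daily means of one weekly recording window."""
    m = _daily_values(daily, variable)
    if m.size < 2:
        raise ValueError("day-to-day SD needs at least two daily means")
    return float(np.std(m, ddof=1))


def day_to_day_cv(daily: list[DailySummary] | np.ndarray,
                  variable: str = "sbp") -> float:
    """Coefficient of variation (%) of the window's daily means."""
    m = _daily_values(daily, variable)
    if m.size < 2:
        raise ValueError("day-to-day CV needs at least two daily means")
    return float(100.0 * np.std(m, ddof=1) / np.mean(m))


def _daily_values(daily, variable: str) -> np.ndarray:
    if len(daily) and isinstance(daily[0], DailySummary):
        attr = f"{variable.lower()}_daily_mean"
        return np.array([getattr(d, attr) for d in daily], dtype=float)
    return np.asarray(daily, dtype=float)


def quartile_spread(day_epochs: np.ndarray, mode: str = "subset_means",
                    strict: bool = True,
                    min_epochs: int = MIN_EPOCHS_PER_DAY) -> float:
    """Difference between the top and bottom quartiles of a day's readings.

    ``mode="subset_means"`` (default): mean of the highest quarter of the
    readings minus mean of the lowest quarter.  ``mode="iqr"``: Q3 - Q1
    boundary quantiles.  Both conventions appear in the BPV literature;
    the subset-mean reading treats "first/fourth quartile" as subsets of
    the data rather than cut points.
    """
    v = np.asarray(day_epochs, dtype=float)
    v = v[~np.isnan(v)]
    if strict and v.size < min_epochs:
        raise ValueError(f"incomplete day: {v.size} epochs (< {min_epochs})")
    if v.size < 4:
        raise ValueError("need at least four readings")
    if mode == "iqr":
        q1, q3 = np.percentile(v, [25, 75])
        return float(q3 - q1)
    if mode != "subset_means":
        raise ValueError("mode must be 'subset_means' or 'iqr'")
    s = np.sort(v)
    q = v.size // 4
    return float(np.mean(s[-q:]) - np.mean(s[:q]))


@dataclass(frozen=True)
class BPVSummary:
    """All variability indices for one rat, week and pressure variable."""

    variable: str                # "sbp", "dbp" or "pp"
    rat_id: int
    week_index: int
    mean_72h: float              # mmHg, mean of the window's 288 epochs
    arv: float                   # mmHg
    sd_24h: float                # mmHg
    weighted_sd_24h: float       # mmHg
    day_to_day_sd: float         # mmHg
    day_to_day_cv: float         # %
    quartile_spread: float       # mmHg


def summarize_window(epochs: TelemetryEpochSeries, variable: str = "sbp",
                     analysis_day: int = 3, lights_on_hour: float = 7.0,
                     quartile_mode: str = "subset_means") -> BPVSummary:
    """Compute the full index bundle for one weekly 72-h window.

    The 24-h indices (SD, ARV, quartile spread, weighted SD) are taken on
    ``analysis_day`` (default: the third and last recording day, two days
    after the discontinuous arm's Monday dose).  Day-to-day indices use
    all three daily means.
    """
    if variable == "pp":
        values = epochs.sbp - epochs.dbp
    else:
        values = getattr(epochs, variable)
    t = epochs.epoch_times_h
    day_idx = np.floor(t / 24.0).astype(int) + 1
    day_mask = day_idx == analysis_day
    if not np.any(day_mask):
        raise ValueError(f"analysis day {analysis_day} not in window")
    day_vals = values[day_mask]
    day_t = t[day_mask]

    clock = (epochs.day_anchor_hour + day_t) % 24.0
    lights = (clock >= lights_on_hour) & (clock < lights_on_hour + 12.0)

    daily = daily_means(epochs)
    if variable == "pp":
        dmeans = np.array([d.sbp_daily_mean - d.dbp_daily_mean for d in daily])
    else:
        dmeans = _daily_values(daily, variable if variable != "pp" else "sbp")

    return BPVSummary(
        variable=variable,
        rat_id=epochs.rat_id,
        week_index=epochs.week_index,
        mean_72h=float(np.nanmean(values)),
        arv=arv(day_vals),
        sd_24h=sd_24h(day_vals),
        weighted_sd_24h=weighted_sd_24h(day_vals[lights], day_vals[~lights]),
        day_to_day_sd=float(np.std(dmeans, ddof=1)),
        day_to_day_cv=float(100.0 * np.std(dmeans, ddof=1) / np.mean(dmeans)),
        quartile_spread=quartile_spread(day_vals, mode=quartile_mode),
    )
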