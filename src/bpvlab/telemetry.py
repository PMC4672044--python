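"""Beat detection and aggregation of readings into the telemetry epoch scheme.

The telemetry protocol records 2 min of signal every 15 min; each 2-min
recording is averaged to a single reading, yielding 4 values per hour,
96 per 24 h and 288 per weekly 72-h window.  Days run from 10:00 to
10:00, the chow-change/recording anchor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .design import StudyDesign, DAY_ANCHOR_HOUR

#: Default study clock origin: a Monday at 10:00 local time.
DEFAULT_START = pd.Timestamp("2015-01-05 10:00:00")


@dataclass
class BeatSeries:
    """Per-beat systolic/diastolic pressure and inter-beat intervals.

    ``ibi_ms[k] = (beat_times[k] - beat_times[k-1]) * 1000``; the first
    entry is NaN (no preceding beat).
    """

    beat_times: np.ndarray      # s
    sbp: np.ndarray             # mmHg
    dbp: np.ndarray             # mmHg
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.sbp = np.asarray(self.sbp, dtype=float)
        self.dbp = np.asarray(self.dbp, dtype=float)
        if not (len(self.beat_times) == len(self.sbp) == len(self.dbp)):
            raise ValueError("beat_times, sbp, dbp must have equal length")
        if len(self.beat_times) > 1 and np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat_times must be strictly increasing")
        if np.any(self.sbp <= self.dbp):
            raise ValueError("per-beat SBP must exceed DBP")

    @property
    def ibi_ms(self) -> np.ndarray:
        out = np.full(len(self.beat_times), np.nan)
        if len(self.beat_times) > 1:
            out[1:] = np.diff(self.beat_times) * 1000.0
        return out

    @property
    def hr_bpm(self) -> np.ndarray:
        return 60000.0 / self.ibi_ms

    def __len__(self) -> int:
        return len(self.beat_times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.beat_times,
            "sbp_mmHg": self.sbp,
            "dbp_mmHg": self.dbp,
            "ibi_ms": self.ibi_ms,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BeatSeries":
        return cls(df["time_s"].to_numpy(), df["sbp_mmHg"].to_numpy(),
                   df["dbp_mmHg"].to_numpy())


@dataclass
class TelemetryEpochSeries:
    """One SBP/DBP/HR reading per scheduled 15-min tick for one rat.

    Times are hours since the window start (itself at the 10:00 anchor);
    missing epochs are NaN, never interpolated.
    """

    epoch_times_h: np.ndarray
    sbp: np.ndarray
    dbp: np.ndarray
    hr: np.ndarray
    day_anchor_hour: float = DAY_ANCHOR_HOUR
    start_time: pd.Timestamp = DEFAULT_START
    rat_id: int = 0
    group: str = ""
    week_index: int = 1

    def __post_init__(self) -> None:
        for name in ("epoch_times_h", "sbp", "dbp", "hr"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.epoch_times_h)
        if not all(len(getattr(self, k)) == n for k in ("sbp", "dbp", "hr")):
            raise ValueError("channel lengths must match epoch_times")

    def __len__(self) -> int:
        return len(self.epoch_times_h)

    def to_frame(self) -> pd.DataFrame:
        ts = self.start_time + pd.to_timedelta(self.epoch_times_h, unit="h")
        return pd.DataFrame({
            "timestamp": ts.strftime("%Y-%m-%dT%H:%M:%S"),
            "sbp_mmHg": self.sbp,
            "dbp_mmHg": self.dbp,
            "hr_bpm": self.hr,
            "rat_id": self.rat_id,
            "group": self.group,
        })


@dataclass(frozen=True)
class DailySummary:
    """Mean pressures for one 10:00-to-10:00 day of a recording window."""

    day_index: int              # 1-based within the window
    sbp_daily_mean: float
    dbp_daily_mean: float
    n_epochs: int


def detect_beats(waveform: np.ndarray, fs: float) -> BeatSeries:
    """Extract per-beat SBP/DBP from a sampled arterial pressure trace.

    Systolic peaks are located by local-maximum search with a refractory
    period of 0.6x the median cycle length (suppresses dicrotic-notch
    double counts); each beat's DBP is the minimum over the preceding
    inter-peak interval.

    Raises ``ValueError`` when no beats can be found (e.g. a flat trace).
    """
    x = np.asarray(waveform, dtype=float)
    if fs < 100.0:
        raise ValueError("sampling rate too low for rat pressure waveforms")
    if x.size < 2 or np.ptp(x) < 1e-9:
        raise ValueError("no beats detected: trace is flat or empty")

    prominence = 0.3 * np.ptp(x)
    peaks, _ = find_peaks(x, prominence=prominence)
    if peaks.size < 2:
        raise ValueError("no beats detected")
    # second pass with the refractory period from the first-pass rhythm
    refractory = 0.6 * float(np.median(np.diff(peaks)))
    peaks, _ = find_peaks(x, prominence=prominence,
                          distance=max(1, int(round(refractory))))
    if peaks.size < 2:
        raise ValueError("no beats detected")

    # DBP: minimum in the interval preceding each peak; first peak has no
    # complete preceding diastole, so it is dropped.
    times, sbp, dbp = [], [], []
    for prev, cur in zip(peaks[:-1], peaks[1:]):
        trough = prev + int(np.argmin(x[prev:cur]))
        times.append(cur / fs)
        sbp.append(x[cur])
        dbp.append(x[trough])
    return BeatSeries(np.array(times), np.array(sbp), np.array(dbp))


def _tick_means(times: np.ndarray, values: np.ndarray,
                ticks_s: np.ndarray, duration_s: float) -> np.ndarray:
    """Mean of ``values`` within each half-open window [tick, tick+duration)."""
    order = np.argsort(times, kind="stable")
    t, v = times[order], values[order]
    lo = np.searchsorted(t, ticks_s, side="left")
    hi = np.searchsorted(t, ticks_s + duration_s, side="left")
    out = np.full(len(ticks_s), np.nan)
    csum = np.concatenate([[0.0], np.nancumsum(v)])
    cnt = np.concatenate([[0], np.cumsum(~np.isnan(v))])
    n = cnt[hi] - cnt[lo]
    with np.errstate(invalid="ignore"):
        out[n > 0] = (csum[hi] - csum[lo])[n > 0] / n[n > 0]
    return out


def epoch_average(readings: "BeatSeries | Mapping[str, np.ndarray]",
                  design: StudyDesign,
                  times_s: np.ndarray | None = None,
                  window_start_s: float = 0.0) -> TelemetryEpochSeries:
    """Average readings into the scheduled 2-min-every-15-min epochs.

    Parameters
    ----------
    readings
        Either a :class:`BeatSeries` or a mapping with keys ``sbp``,
        ``dbp`` and optionally ``hr`` (then ``times_s`` is required).
    design
        Supplies the epoch interval/duration and window length.
    window_start_s
        Time of the first scheduled tick on the readings' clock.

    Ticks whose 2-min window contains no reading are reported as NaN.
    """
    if isinstance(readings, BeatSeries):
        times = readings.beat_times
        channels = {"sbp": readings.sbp, "dbp": readings.dbp,
                    "hr": readings.hr_bpm}
    else:
        if times_s is None:
            raise ValueError("times_s is required for mapping input")
        times = np.asarray(times_s, dtype=float)
        channels = {k: np.asarray(v, dtype=float) for k, v in readings.items()}
        channels.setdefault("hr", np.full(len(times), np.nan))

    n = design.epochs_per_window
    ticks = window_start_s + np.arange(n) * design.epoch_interval_min * 60.0
    dur = design.epoch_duration_min * 60.0
    if times.size == 0 or times[-1] < ticks[0] or times[0] >= ticks[-1] + dur:
        raise ValueError("readings and epoch schedule do not overlap")

    means = {k: _tick_means(times, v, ticks, dur) for k, v in channels.items()}
    return TelemetryEpochSeries(
        epoch_times_h=(ticks - window_start_s) / 3600.0,
        sbp=means["sbp"], dbp=means["dbp"], hr=means["hr"],
    )


def daily_means(epochs: TelemetryEpochSeries,
                strict: bool = False,
                min_epochs: int = 1) -> list[DailySummary]:
    """Mean SBP/DBP per 10:00-to-10:00 day of the recording window.

    ``n_epochs`` counts epochs with a valid SBP reading so callers can
    enforce completeness (96/day when nothing is missing).  With
    ``strict=True`` a window containing no complete day is an error.
    """
    day_idx = np.floor(epochs.epoch_times_h / 24.0).astype(int)
    out = []
    for d in np.unique(day_idx):
        m = day_idx == d
        valid = m & ~np.isnan(epochs.sbp)
        n = int(valid.sum())
        if n < min_epochs:
            continue
        out.append(DailySummary(
            day_index=int(d) + 1,
            sbp_daily_mean=float(np.mean(epochs.sbp[valid])),
            dbp_daily_mean=float(np.mean(epochs.dbp[valid])),
            n_epochs=n,
        ))
    per_day = int(round(24.0 * 60.0 / (np.median(np.diff(epochs.epoch_times_h)) * 60.0))) \
        if len(epochs) > 1 else 96
    if strict and not any(s.n_epochs >= per_day for s in out):
        raise ValueError("no complete day in recording window")
    return out
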