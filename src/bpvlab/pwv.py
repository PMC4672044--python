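"""Foot-to-foot pulse wave velocity and derived hemodynamic indices.

PWV is the speed at which the pressure pulse travels along the aorta —
the reference index of aortic stiffness.  With two catheters a known
distance apart, the transit time is the delay between the "feet"
(upstroke onsets) of the proximal and distal waves; the foot of each
beat is located by the intersecting-tangent method: the crossing of the
horizontal line through the diastolic minimum with the tangent at the
point of maximum upstroke slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks, savgol_filter

#: mmHg -> dyn/cm^2
MMHG_TO_DYN_CM2 = 1333.22
#: Blood density, g/cm^3
BLOOD_DENSITY = 1.05


@dataclass
class DualPressureWaveform:
    """Simultaneously sampled proximal and distal aortic pressure traces.

    ``distance_cm`` is the catheter-tip separation (in practice the mean
    of three measurements).
    """

    proximal: np.ndarray
    distal: np.ndarray
    fs: float
    distance_cm: float
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.proximal = np.asarray(self.proximal, dtype=float)
        self.distal = np.asarray(self.distal, dtype=float)
        if self.proximal.shape != self.distal.shape:
            raise ValueError("traces must have equal length")
        if self.fs <= 0 or self.distance_cm <= 0:
            raise ValueError("fs and distance must be positive")


@dataclass(frozen=True)
class PWVResult:
    pwv_cm_s: float
    transit_time_ms: float        # median over paired beats
    n_beats: int                  # number of valid pairs
    n_dropped: int                # nonpositive-delay pairs discarded
    per_beat_delays_ms: tuple[float, ...]
    beta_index: float | None = None


def detect_foot(trace: np.ndarray, fs: float, method: str = "tangent",
                smooth_ms: float = 4.0, lowpass_hz: float | None = 40.0
                ) -> np.ndarray:
    """Per-beat foot times (s) of a sampled pressure trace.

    ``method="tangent"`` (default): intersecting-tangent foot — for each
    upstroke, the line through the point of maximum dP/dt intersected
    with the horizontal through the preceding diastolic minimum; the
    intersection gives sub-sample timing.  ``method="d2max"`` uses the
    maximum of the second derivative instead.

    Noise handling: a zero-phase low-pass at ``lowpass_hz`` (the rat
    upstroke's bandwidth; zero phase so no timing shift) followed by a
    short Savitzky-Golay derivative over ``smooth_ms``.  Because the
    transit time is the *difference* of two foot sequences filtered
    identically, the residual shape bias of the filter cancels.
    """
    x = np.asarray(trace, dtype=float)
    if x.size < 10 or np.ptp(x) < 1e-9:
        raise ValueError("upstroke not found: trace is flat or too short")
    if fs < 500.0:
        raise ValueError("fs must be >= 500 Hz for foot timing")

    if lowpass_hz is not None and lowpass_hz < fs / 2.0:
        b, a = butter(4, lowpass_hz / (fs / 2.0))
        x = filtfilt(b, a, x)
    win = max(5, int(round(smooth_ms * fs / 1000.0)) | 1)
    xs = savgol_filter(x, win, polyorder=3)
    dx = savgol_filter(x, win, polyorder=3, deriv=1) * fs   # mmHg/s

    prom = 0.4 * np.max(dx)     # candidate upstrokes: maxima of dP/dt
    if prom <= 0:
        raise ValueError("upstroke not found")
    # refractory period from the systolic rhythm itself
    peaks, _ = find_peaks(xs, prominence=0.3 * np.ptp(xs))
    if peaks.size >= 2:
        min_dist = max(1, int(round(0.6 * np.median(np.diff(peaks)))))
    else:
        min_dist = max(1, int(round(0.3 * fs * 60.0 / 400.0)))
    slopes, _ = find_peaks(dx, prominence=prom, distance=min_dist)
    if slopes.size == 0:
        raise ValueError("upstroke not found")

    feet = []
    for m in slopes:
        back = int(round(0.4 * min_dist / 0.6))
        lo = max(0, m - back)
        seg = xs[lo:m + 1]
        if seg.size == 0:
            continue
        p_min = float(np.min(seg))
        slope = dx[m]
        if slope <= 0:
            continue
        if method == "tangent":
            t_foot = m / fs - (xs[m] - p_min) / slope
        elif method == "d2max":
            d2 = np.diff(dx[lo:m + 1])
            if d2.size == 0:
                continue
            t_foot = (lo + int(np.argmax(d2))) / fs
        else:
            raise ValueError("method must be 'tangent' or 'd2max'")
        feet.append(t_foot)
    if not feet:
        raise ValueError("upstroke not found")
    return np.asarray(feet)


def transit_time(prox_feet: np.ndarray, dist_feet: np.ndarray
                 ) -> tuple[float, np.ndarray, int]:
    """Median foot-to-foot delay (ms) between paired beats.

    Each distal foot is paired with the nearest preceding proximal foot
    within one beat period; pairs with nonpositive delay are dropped and
    counted.  Returns ``(median_ms, per_beat_delays_ms, n_dropped)``.
    """
    prox = np.sort(np.asarray(prox_feet, dtype=float))
    dist = np.sort(np.asarray(dist_feet, dtype=float))
    if prox.size < 1 or dist.size < 1:
        raise ValueError("need feet from both traces")
    period = float(np.median(np.diff(prox))) if prox.size > 1 else np.inf

    delays = []
    dropped = 0
    idx = np.searchsorted(prox, dist, side="right") - 1
    for j, i in enumerate(idx):
        if i < 0:
            dropped += 1
            continue
        d = dist[j] - prox[i]
        if d <= 0 or d >= period:
            dropped += 1
            continue
        delays.append(d * 1000.0)
    if not delays:
        raise ValueError("no valid foot pairs (nonpositive delays?)")
    return float(np.median(delays)), np.asarray(delays), dropped


def pwv(distance_cm: float, transit_time_ms: float) -> float:
    """Pulse wave velocity, cm/s = distance / transit time."""
    if distance_cm <= 0 or transit_time_ms <= 0:
        raise ValueError("distance and transit time must be positive")
    return distance_cm / (transit_time_ms / 1000.0)


def estimate_pwv(wave: DualPressureWaveform, method: str = "tangent",
                 dbp_mmHg: float | None = None) -> PWVResult:
    """Foot-to-foot PWV from a dual-site pressure recording."""
    prox_feet = detect_foot(wave.proximal, wave.fs, method=method)
    dist_feet = detect_foot(wave.distal, wave.fs, method=method)
    tt, delays, dropped = transit_time(prox_feet, dist_feet)
    v = pwv(wave.distance_cm, tt)
    beta = beta_index(v, dbp_mmHg) if dbp_mmHg is not None else None
    return PWVResult(pwv_cm_s=v, transit_time_ms=tt, n_beats=len(delays),
                     n_dropped=dropped, per_beat_delays_ms=tuple(delays),
                     beta_index=beta)


def pulse_pressure(sbp: float, dbp: float) -> float:
    """PP = SBP - DBP, mmHg."""
    if sbp <= dbp:
        raise ValueError("SBP must exceed DBP")
    return sbp - dbp


def mean_bp(sbp: float, dbp: float) -> float:
    """MBP = DBP + PP/3 (the one-third rule), mmHg."""
    return dbp + pulse_pressure(sbp, dbp) / 3.0


def beta_index(pwv_cm_s: float, dbp_mmHg: float,
               blood_density: float = BLOOD_DENSITY) -> float:
    """Pressure-normalized stiffness index from PWV and diastolic pressure.

    Convention: ``beta = 2 * rho * PWV^2 / DBP`` (Bramwell-Hill form)
    with pressure converted to dyn/cm^2, dimensionless.  Reported values
    must always be read together with this convention string — different
    groups use different constants for the same name.
    """
    if pwv_cm_s <= 0 or dbp_mmHg <= 0:
        raise ValueError("pwv and dbp must be positive")
    return 2.0 * blood_density * pwv_cm_s ** 2 / (dbp_mmHg * MMHG_TO_DYN_CM2)


BETA_CONVENTION = "2*rho*PWV^2/DBP, rho=1.05 g/cm^3, DBP in dyn/cm^2"
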