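"""Synthetic SHR telemetry with known ground truth.

Three generators mirror the three kinds of raw data an implanted
telemetry study produces:

* epoch-level SBP/DBP/HR series over each weekly 72-h recording window,
  driven by a one-compartment valsartan PK model with an Emax effect;
* beat-level SBP/IBI series carrying injected LF (vasomotor) and HF
  (respiratory) oscillations of known variance, for spectral recovery;
* dual-site aortic pressure waveforms with a known transit delay, for
  foot-to-foot pulse wave velocity.

Every stochastic term is reproducible from ``(seed, group, rat_id)``;
adding rats never perturbs existing streams.
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd

from .design import (DAY_ANCHOR_HOUR, HemodynamicModel, PKPDParams,
                     StudyDesign, default_pk_for_group)
from .telemetry import DEFAULT_START, BeatSeries, TelemetryEpochSeries


def _rat_rng(seed: int, group: str, rat_id: int) -> np.random.Generator:
    """Per-rat substream: hash (seed, group, rat_id) into a SeedSequence."""
    gh = zlib.crc32(group.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence((seed, gh, rat_id)))


# ---------------------------------------------------------------------------
# pharmacokinetics

def pk_concentration(pk: PKPDParams, t_h: np.ndarray) -> np.ndarray:
    """Plasma concentration at times ``t_h`` (hours from treatment start).

    One-compartment, first-order absorption and elimination; each dose
    contributes ``fraction * (exp(-ke dt) - exp(-ka dt)) / peak`` so that
    a single full dose peaks at exactly 1.  Concentration is zero before
    the first dose.  ``ka == ke`` uses the limiting form ``dt exp(-ke dt)``.
    """
    t = np.atleast_1d(np.asarray(t_h, dtype=float))
    ka, ke = pk.absorption_rate, pk.ke
    if ka <= 0 or ke <= 0:
        raise ValueError("absorption and elimination rates must be positive")

    if abs(ka - ke) < 1e-12 * ke:
        tmax = 1.0 / ke
        peak = tmax * np.exp(-ke * tmax)

        def shape(dt):
            return dt * np.exp(-ke * dt)
    else:
        tmax = np.log(ka / ke) / (ka - ke)
        peak = np.exp(-ke * tmax) - np.exp(-ka * tmax)

        def shape(dt):
            return np.exp(-ke * dt) - np.exp(-ka * dt)

    c = np.zeros_like(t)
    for dose in pk.doses:
        dt = t - dose.time_h
        live = dt > 0
        if np.any(live):
            c[live] += dose.fraction * shape(dt[live]) / peak
    return c if np.ndim(t_h) else float(c[0])


def effect_site_concentration(pk: PKPDParams, t_h: np.ndarray,
                              ke0: float | None) -> np.ndarray:
    """Biophase concentration for a first-order effect compartment.

    ``ke0=None`` means the effect tracks plasma directly.  The closed
    form superposes, per dose, the triple exponential obtained by
    filtering the Bateman profile through ``dCe/dt = ke0 (C - Ce)``.
    """
    if ke0 is None:
        return pk_concentration(pk, t_h)
    t = np.atleast_1d(np.asarray(t_h, dtype=float))
    ka, ke = pk.absorption_rate, pk.ke
    for k in (ka, ke):
        if abs(ke0 - k) < 1e-9 * k:   # keep the three rates distinct
            ke0 = ke0 * (1.0 + 1e-6)
    tmax = np.log(ka / ke) / (ka - ke)
    peak = np.exp(-ke * tmax) - np.exp(-ka * tmax)

    ce = np.zeros_like(t)
    for dose in pk.doses:
        dt = t - dose.time_h
        live = dt > 0
        if not np.any(live):
            continue
        d = dt[live]
        e_ke0 = np.exp(-ke0 * d)
        term = ((np.exp(-ke * d) - e_ke0) / (ke0 - ke)
                - (np.exp(-ka * d) - e_ke0) / (ke0 - ka))
        ce[live] += dose.fraction * ke0 * term / peak
    return ce if np.ndim(t_h) else float(ce[0])


def drug_effect(pk: PKPDParams, t_h: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(SBP, DBP) lowering in mmHg at ``t_h``: Emax * Ce / (Ce + EC50)."""
    ce_s = effect_site_concentration(pk, t_h, pk.ke0_sbp)
    ce_d = effect_site_concentration(pk, t_h, pk.ke0_dbp)
    return (pk.emax_sbp * ce_s / (ce_s + pk.ec50),
            pk.emax_dbp * ce_d / (ce_d + pk.ec50_dbp))


# ---------------------------------------------------------------------------
# epoch-level telemetry

def circadian_term(model: HemodynamicModel, t_abs_h: np.ndarray,
                   anchor_hour: float = DAY_ANCHOR_HOUR) -> np.ndarray:
    """SBP circadian cosine at absolute study time (h from the anchor)."""
    clock = (anchor_hour + t_abs_h) % 24.0
    return model.circadian_amplitude * np.cos(
        2.0 * np.pi * (clock - model.acrophase_hour) / 24.0)


def deterministic_epoch_means(model: HemodynamicModel, pk: PKPDParams,
                              t_abs_h: np.ndarray,
                              anchor_hour: float = DAY_ANCHOR_HOUR
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form (SBP, DBP) with all stochastic terms off."""
    circ = circadian_term(model, t_abs_h, anchor_hour)
    eff_s, eff_d = drug_effect(pk, t_abs_h)
    sbp = model.sbp_baseline + circ - eff_s
    dbp = model.dbp_baseline + model.dbp_circadian_ratio * circ - eff_d
    return sbp, dbp


def simulate_epoch_series(design: StudyDesign, model: HemodynamicModel,
                          pk: PKPDParams, group: str, rat_id: int,
                          seed: int | None = None) -> list[TelemetryEpochSeries]:
    """Simulate one rat's weekly 72-h epoch series for the whole study.

    Each week contributes 288 epochs (4/h for 3 days).  SBP is
    baseline + circadian + drug effect + day random intercept + noise;
    DBP analogously with its own Emax and a correlated day intercept.
    Parameter sets that would produce SBP <= DBP (or non-physiological
    DBP) are rejected rather than clipped, so the stochastic structure
    the recovery tests rely on stays intact.
    """
    if group not in design.groups:
        raise ValueError(f"group {group!r} not in design")
    seed = design.seed if seed is None else seed
    rng = _rat_rng(seed, group, rat_id)

    n_days = design.treatment_weeks * 7
    # closed-form Cholesky factor of the bivariate day-effect covariance
    # (valid for sd = 0 too)
    rho = model.day_effect_corr
    chol = model.day_effect_sd * np.array(
        [[1.0, 0.0], [rho, np.sqrt(1.0 - rho ** 2)]])
    day_eff = rng.standard_normal((n_days, 2)) @ chol.T

    n = design.epochs_per_window
    ticks_h = np.arange(n) * design.epoch_interval_min / 60.0
    mid_h = ticks_h + design.epoch_duration_min / 120.0
    out = []
    for week in range(design.treatment_weeks):
        t_abs = week * 168.0 + mid_h
        sbp_det, dbp_det = deterministic_epoch_means(
            model, pk, t_abs, design.day_anchor_hour)
        day_idx = np.floor(t_abs / 24.0).astype(int)
        noise = rng.standard_normal((3, n))
        rho = model.epoch_noise_corr
        z_dbp = rho * noise[0] + np.sqrt(1.0 - rho ** 2) * noise[1]
        sbp = sbp_det + day_eff[day_idx, 0] + model.epoch_noise_sd * noise[0]
        dbp = dbp_det + day_eff[day_idx, 1] + model.epoch_noise_sd * z_dbp
        hr = model.hr_baseline + model.hr_noise_sd * noise[2]
        if np.any(sbp <= dbp) or np.any(dbp <= 20.0):
            raise ValueError(
                "non-physiological pressures generated; adjust model "
                "parameters (values are rejected, never clipped)")
        out.append(TelemetryEpochSeries(
            epoch_times_h=ticks_h, sbp=sbp, dbp=dbp, hr=hr,
            day_anchor_hour=design.day_anchor_hour,
            start_time=DEFAULT_START + pd.Timedelta(hours=week * 168.0),
            rat_id=rat_id, group=group, week_index=week + 1))
    return out


def simulate_group_series(design: StudyDesign, model: HemodynamicModel,
                          group: str, pk: PKPDParams | None = None,
                          seed: int | None = None
                          ) -> dict[int, list[TelemetryEpochSeries]]:
    """Epoch series for every rat of one arm, keyed by rat id."""
    pk_full = default_pk_for_group(group, design.treatment_weeks, pk)
    return {rat: simulate_epoch_series(design, model, pk_full, group, rat, seed)
            for rat in range(design.n_rats_per_group)}


# ---------------------------------------------------------------------------
# beat-level telemetry

def simulate_beat_series(model: HemodynamicModel, duration_s: float = 120.0,
                         seed: int | None = None,
                         sbp_level: float | None = None) -> BeatSeries:
    """Beat-by-beat SBP/IBI with injected narrow-band oscillations.

    IBI = baseline + HF sinusoid (+ jitter); SBP = level + LF sinusoid
    (+ noise).  The injected band variances (A^2/2 for each sinusoid)
    are stored in ``ground_truth`` for spectral recovery tests.
    """
    if duration_s < 60.0:
        raise ValueError("need at least 60 s of beats")
    beat_rate = model.hr_baseline / 60.0
    if model.hf_freq >= 0.5 * beat_rate:
        raise ValueError("hf_freq at or above half the beat rate: aliased")
    rng = np.random.default_rng(seed)
    ibi0 = 60000.0 / model.hr_baseline
    level = model.sbp_baseline if sbp_level is None else sbp_level

    n_max = int(np.ceil(duration_s * beat_rate * 1.5)) + 2
    times = np.empty(n_max)
    times[0] = 0.0
    k = 0
    while times[k] < duration_s and k + 1 < n_max:
        ibi = (ibi0
               + model.hf_ibi_amplitude * np.sin(2 * np.pi * model.hf_freq * times[k])
               + model.ibi_jitter_sd * rng.standard_normal())
        times[k + 1] = times[k] + ibi / 1000.0
        k += 1
    times = times[:k + 1]
    sbp = (level
           + model.lf_amplitude * np.sin(2 * np.pi * model.lf_freq * times)
           + model.beat_sbp_noise_sd * rng.standard_normal(times.size))
    dbp = np.full_like(times, model.dbp_baseline)
    truth = {
        "lf_var_mmHg2": model.lf_amplitude ** 2 / 2.0,
        "hf_var_ms2": model.hf_ibi_amplitude ** 2 / 2.0,
        "lf_freq_hz": model.lf_freq,
        "hf_freq_hz": model.hf_freq,
        "mean_ibi_ms": ibi0,
    }
    return BeatSeries(times, sbp, dbp, ground_truth=truth)


# ---------------------------------------------------------------------------
# dual-site pressure waveforms

def pulse_template(phase_s: np.ndarray, period_s: float, pp: float,
                   dbp: float, upstroke_frac: float = 0.15) -> np.ndarray:
    """Periodic pressure pulse: raised-cosine upstroke, exponential decay.

    The diastolic decay is renormalized to land exactly on ``dbp`` at the
    end of the cycle, so the waveform is continuous and its foot (cycle
    start) sits exactly at ``dbp``.
    """
    t_up = upstroke_frac * period_s
    tau = (period_s - t_up) / 4.0
    phi = np.mod(phase_s, period_s)
    up = phi < t_up
    out = np.empty_like(phi)
    out[up] = dbp + pp * 0.5 * (1.0 - np.cos(np.pi * phi[up] / t_up))
    e_end = np.exp(-(period_s - t_up) / tau)
    decay = (np.exp(-(phi[~up] - t_up) / tau) - e_end) / (1.0 - e_end)
    out[~up] = dbp + pp * decay
    return out


def simulate_dual_pressure(pp: float, dbp: float, hr: float, delay_s: float,
                           distance_cm: float, fs: float = 2000.0,
                           damping: float = 0.0, noise_sd: float = 0.0,
                           duration_s: float = 10.0,
                           seed: int | None = None):
    """Proximal/distal aortic pressure pair with a known transit delay.

    The distal trace is the proximal template delayed by ``delay_s`` with
    pulse pressure scaled by ``(1 - damping)``; white measurement noise
    is optional.  True delay (and hence true PWV = distance/delay) is
    carried as ground truth.
    """
    from .pwv import DualPressureWaveform   # local import to avoid a cycle

    period = 60.0 / hr
    if fs < 500.0:
        raise ValueError("fs must be >= 500 Hz for foot timing")
    if not 0.0 < delay_s < period:
        raise ValueError("delay must lie strictly inside one beat period")
    if not 0.0 <= damping < 1.0:
        raise ValueError("damping must be in [0, 1)")
    n_beats = max(2, int(np.floor(duration_s / period)))
    n = int(round(n_beats * period * fs))
    t = np.arange(n) / fs
    prox = pulse_template(t, period, pp, dbp)
    dist = pulse_template(t - delay_s, period, pp * (1.0 - damping), dbp)
    if noise_sd > 0.0:
        rng = np.random.default_rng(seed)
        prox = prox + noise_sd * rng.standard_normal(n)
        dist = dist + noise_sd * rng.standard_normal(n)
    onsets = np.arange(n_beats) * period
    # where the intersecting-tangent method puts the foot of a
    # raised-cosine upstroke: t_up * (1/2 - 1/pi) past the onset
    tangent_offset = 0.15 * period * (0.5 - 1.0 / np.pi)
    truth = {"delay_s": delay_s,
             "pwv_cm_s": distance_cm / delay_s,
             "onset_times_s": onsets,
             "foot_times_s": onsets + tangent_offset}
    return DualPressureWaveform(proximal=prox, distal=dist, fs=fs,
                                distance_cm=distance_cm, ground_truth=truth)
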