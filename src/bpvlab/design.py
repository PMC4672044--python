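"""Study design, pharmacokinetic/pharmacodynamic and hemodynamic parameter sets.

The defaults describe a chronic telemetry study in spontaneously
hypertensive rats (SHR): three arms (placebo, continuous valsartan,
discontinuous valsartan 30 mg/kg/d), 8 weeks of treatment, blood pressure
recorded each week from Monday 10:00 to Thursday 10:00 as 2-min averages
every 15 min (4/h, 96/day, 288 per 72-h window).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

PLACEBO = "placebo"
CONTINUOUS = "continuous"
DISCONTINUOUS = "discontinuous"

#: Hours in the weekly recording window (Mon 10:00 -> Thu 10:00).
RECORDING_WINDOW_H = 72.0
#: Day boundaries are anchored at this clock hour (treatment/recording anchor).
DAY_ANCHOR_HOUR = 10.0


@dataclass(frozen=True)
class DoseEvent:
    """A single oral dose: time offset from treatment start, and the
    fraction of the nominal daily dose delivered."""

    time_h: float
    fraction: float = 1.0


def chow_doses(days: Sequence[int], n_weeks: int, doses_per_day: int = 12) -> list[DoseEvent]:
    """Dose schedule approximating ad libitum medicated chow.

    Intake over each exposure day is represented as ``doses_per_day``
    equal sub-doses spread over 24 h starting at the 10:00 chow change.

    Parameters
    ----------
    days
        Weekdays of exposure, 0 = Monday (the day chow is switched at 10:00).
    n_weeks
        Number of treatment weeks to schedule.
    doses_per_day
        Granularity of the intake approximation.
    """
    frac = 1.0 / doses_per_day
    step = 24.0 / doses_per_day
    out = []
    for w in range(n_weeks):
        for d in days:
            t0 = w * 168.0 + d * 24.0
            out.extend(DoseEvent(t0 + k * step, frac) for k in range(doses_per_day))
    return out


def continuous_schedule(n_weeks: int) -> list[DoseEvent]:
    """Valsartan chow every day of the week."""
    return chow_doses(range(7), n_weeks)


def discontinuous_schedule(n_weeks: int) -> list[DoseEvent]:
    """Valsartan chow for 24 h starting Monday and Thursday 10:00 only."""
    return chow_doses((0, 3), n_weeks)


@dataclass(frozen=True)
class StudyDesign:
    """Arms, sample size and the weekly telemetry sampling scheme."""

    groups: tuple[str, ...] = (PLACEBO, CONTINUOUS, DISCONTINUOUS)
    n_rats_per_group: int = 5
    treatment_weeks: int = 8
    epoch_interval_min: float = 15.0
    epoch_duration_min: float = 2.0
    recording_window_h: float = RECORDING_WINDOW_H
    day_anchor_hour: float = DAY_ANCHOR_HOUR
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.epoch_duration_min < self.epoch_interval_min:
            raise ValueError("need epoch_interval > epoch_duration > 0")
        if self.treatment_weeks < 1:
            raise ValueError("treatment_weeks must be >= 1")
        if self.recording_window_h <= 0:
            raise ValueError("recording window must be positive")

    @property
    def epochs_per_window(self) -> int:
        return int(round(self.recording_window_h * 60.0 / self.epoch_interval_min))

    @property
    def epochs_per_day(self) -> int:
        return int(round(24.0 * 60.0 / self.epoch_interval_min))


@dataclass(frozen=True)
class PKPDParams:
    """One-compartment oral PK with an Emax effect on SBP and DBP.

    Concentration is expressed in units of the peak reached by a single
    full dose (so ``ec50`` is a fraction of that peak).  Separate effect-
    compartment equilibration rates let the SBP response outlast plasma
    drug, while DBP tracks washout more closely — the mechanism behind
    the diastolic rebound seen two days after withdrawal.
    """

    dose_mg_per_kg: float = 30.0
    absorption_rate: float = 1.0         # ka, 1/h
    elimination_halflife: float = 6.0    # h, in the rat's reported 5-7 h range
    emax_sbp: float = 33.0               # mmHg, maximal SBP lowering
    emax_dbp: float = 42.0               # mmHg, maximal DBP lowering
    ec50: float = 0.10                   # SBP EC50, fraction of single-dose peak
    ec50_dbp: float = 0.50               # DBP EC50 (less saturated response)
    ke0_sbp: float | None = 0.02         # 1/h, slow effect equilibration
    ke0_dbp: float | None = 0.02         # None = effect tracks plasma directly
    doses: tuple[DoseEvent, ...] = ()

    def __post_init__(self) -> None:
        if self.elimination_halflife <= 0:
            raise ValueError("elimination_halflife must be positive")
        if self.ec50 <= 0 or self.ec50_dbp <= 0:
            raise ValueError("ec50 must be positive")
        if min(self.emax_sbp, self.emax_dbp) < 0:
            raise ValueError("emax must be non-negative")

    @property
    def ke(self) -> float:
        return float(np.log(2.0) / self.elimination_halflife)

    def with_schedule(self, doses: Sequence[DoseEvent]) -> "PKPDParams":
        return replace(self, doses=tuple(doses))


@dataclass(frozen=True)
class HemodynamicModel:
    """Deterministic + stochastic structure of the simulated BP signal.

    Epoch-level SBP is baseline + nocturnal circadian cosine + drug effect
    + a per-day random intercept + white epoch noise; DBP is analogous
    with its own baseline, Emax and a scaled circadian swing.  Beat-level
    structure (LF vasomotor SBP oscillation, HF respiratory IBI
    oscillation) feeds the spectral indices.
    """

    sbp_baseline: float = 160.3          # mmHg, untreated SHR 72-h mean
    dbp_baseline: float = 114.3          # mmHg
    circadian_amplitude: float = 13.0    # mmHg, SBP cosine amplitude
    dbp_circadian_ratio: float = 0.8     # DBP swing relative to SBP
    acrophase_hour: float = 1.0          # clock time of the nocturnal BP peak
    day_effect_sd: float = 0.7           # mmHg, between-day random intercept
    day_effect_corr: float = 0.8         # SBP/DBP day-effect correlation
    epoch_noise_sd: float = 7.0          # mmHg, residual epoch-to-epoch noise
    epoch_noise_corr: float = 0.8        # SBP/DBP epoch-noise correlation
    hr_baseline: float = 320.0           # bpm
    hr_noise_sd: float = 8.0             # bpm, epoch-level HR noise
    lf_amplitude: float = 3.0            # mmHg, SBP oscillation at lf_freq
    lf_freq: float = 0.4                 # Hz, sympathetic vasomotor band
    hf_ibi_amplitude: float = 4.0        # ms, IBI oscillation at hf_freq
    hf_freq: float = 1.5                 # Hz, respiratory band
    ibi_jitter_sd: float = 1.5           # ms, beat-to-beat IBI noise
    beat_sbp_noise_sd: float = 1.0       # mmHg, beat-to-beat SBP noise

    def __post_init__(self) -> None:
        if self.sbp_baseline <= self.dbp_baseline:
            raise ValueError("sbp_baseline must exceed dbp_baseline")
        for name in ("day_effect_sd", "epoch_noise_sd", "hr_noise_sd",
                     "ibi_jitter_sd", "beat_sbp_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.2 <= self.lf_freq <= 0.6:
            raise ValueError("lf_freq must lie in the 0.2-0.6 Hz LF band")
        if not 1.0 <= self.hf_freq <= 2.5:
            raise ValueError("hf_freq must lie in the 1.0-2.5 Hz HF band")
        if not -1.0 <= self.day_effect_corr <= 1.0:
            raise ValueError("day_effect_corr must be a correlation")


def default_pk_for_group(group: str, n_weeks: int,
                         base: PKPDParams | None = None) -> PKPDParams:
    """Attach the arm's dosing schedule to a PK/PD parameter set."""
    pk = base or PKPDParams()
    if group == PLACEBO:
        return pk.with_schedule(())
    if group == CONTINUOUS:
        return pk.with_schedule(continuous_schedule(n_weeks))
    if group == DISCONTINUOUS:
        return pk.with_schedule(discontinuous_schedule(n_weeks))
    raise ValueError(f"unknown group {group!r}")
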