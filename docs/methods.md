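# Methods

## The experiment being modeled

Three arms of male SHR: placebo chow, continuous valsartan chow
(30 mg/kg/d), and discontinuous valsartan (medicated chow for 24 h
starting Monday and Thursday 10:00, normal chow otherwise). Telemetered
aortic pressure is recorded weekly from Monday 10:00 to Thursday 10:00
for 8 weeks as 2-min averages every 15 min — 4 readings/h, 96/day and
288 per window. Days are the [10:00, 10:00) intervals of that window.
Aortic stiffness is measured once, under anesthesia, as foot-to-foot
pulse wave velocity between two intra-aortic catheters a measured
distance apart.

## Synthetic telemetry generator

The generator's defaults *are* the study conditions: 3 groups × 5 rats
× 8 weeks, 15-min epochs of 2-min duration, valsartan elimination
half-life 6 h (midpoint of the rat's reported 5–7 h range), first-order
absorption at 1 h⁻¹, dose 30 mg/kg/d.

**Pharmacokinetics.** One compartment, first-order absorption and
elimination; concentration is a superposition over dose events of
Bateman profiles normalized so a single full dose peaks at 1 (so EC50
values are fractions of that peak). Chow intake is approximated as 12
equal sub-doses spread over each exposure day. After the discontinuous
arm's 48-h withdrawal the residue is 2^(−48/t½) of the elimination
envelope — 0.4% at the 6-h default, i.e. washout is effectively
complete, which is the premise of the design. (At the extreme 7-h
half-life the residue is 0.86%; "complete" is an approximation there by
arithmetic necessity.)

**Pharmacodynamics.** Effect = Emax·Ce/(Ce + EC50), subtracted from the
baseline pressure. Two choices reproduce the characteristic
systolic/diastolic dissociation (SBP stays lowered through the washout
while DBP rebounds on day 3):

* a common effect compartment, dCe/dt = ke0·(C − Ce) with ke0 =
  0.02 h⁻¹, making the response much more persistent than plasma drug;
* SBP operating near saturation (EC50 = 0.10 of a single-dose peak,
  Emax 33 mmHg) while DBP responds almost linearly (EC50 = 0.50,
  Emax 42 mmHg), so concentration swings pass through to DBP but barely
  move SBP.

Defaults were calibrated once, against the published group means only
(placebo 160.3/114.3 mmHg; continuous 132.8/93.3; discontinuous
141.3/105.6; day-to-day SDs of order 1 mmHg in stable arms and 2–3 mmHg
in the discontinuous arm). With the defaults the deterministic model
gives continuous 133.0/93.8 and discontinuous 141.6/105.4 with a day-3
diastolic rebound of ≈2.5 mmHg. One known cosmetic mismatch: because
chow absorption ramps up over the dosing day, the deterministic
discontinuous DBP day pattern is (high, low, high) rather than
(low, low, high); the defining features — day 3 > day 2, correct means,
correct day-to-day SD/CV magnitude — hold.

**Stochastic structure.** Per rat: (i) a per-calendar-day bivariate
random intercept (SD 0.7 mmHg, SBP/DBP correlation 0.8) — the carrier of
"true" day-to-day variability in the placebo arm; (ii) epoch-level
Gaussian noise (SD 7 mmHg, SBP/DBP correlation 0.8 — telemetry epochs
are short averages of a strongly common-mode signal); (iii) a circadian
cosine (13 mmHg amplitude on SBP, ×0.8 on DBP, nocturnal acrophase
01:00 — rats are dark-active). These give 24-h SDs of ~12 (SBP) and ~10
(DBP) mmHg and ARVs of ~8 mmHg, the observed order. Pressures that
would violate SBP > DBP are rejected, never clipped, so the
distributional assumptions of the recovery tests stay intact.

**Reproducibility.** Every rat's stream is seeded from
`(seed, crc32(group), rat_id)` through a `SeedSequence`, so runs are
bit-identical under a fixed seed and adding rats never perturbs
existing ones.

**Beat-level and waveform generators.** Beat series: IBI = 60000/HR +
HF sinusoid + jitter, advanced beat by beat; per-beat SBP = level + LF
sinusoid + noise; the injected band variances (A²/2) are stored as
ground truth. Dual-site waveforms: a raised-cosine upstroke (15% of the
cycle) with an exponential diastolic decay renormalized to land exactly
on DBP, the distal trace delayed by the true transit time and damped in
pulse pressure; the generator records both the upstroke onsets and the
analytic intersecting-tangent foot positions
(onset + t_up·(1/2 − 1/π)).

## What the generator does not emulate

Real telemetry contains artifacts, arrhythmic beats, missing epochs
from radio dropouts, drifting baselines, aging-related HR decline and
inter-rat heterogeneity in circadian shape; the pressure pulse is not a
fixed template and PWV varies with distending pressure within the
beat. Passing recovery tests therefore demonstrates correctness of the
estimators on clean, stationary, well-specified signals — not
robustness to every pathology of real recordings (beyond the white-noise
and refractory-period contracts explicitly tested).

## Analysis choices

* **Epoch windows** are half-open [t, t + 2 min); ticks with no reading
  are NaN and are never interpolated. ARV breaks its chain at gaps
  instead of inflating weights. 24-h indices refuse days with fewer
  than 90 of 96 epochs (configurable).
* **SDs** use the n−1 denominator throughout. Day-to-day CV is computed
  per rat (100·SD/mean of that rat's three daily means) before any
  group averaging — group-level CV of group means is a different,
  smaller number.
* **24-h indices** default to the third recording day (two days after
  the discontinuous arm's Monday dose, where the rebound lives);
  `analysis_day` is configurable.
* **Quartile spread** defaults to mean(top quarter) − mean(bottom
  quarter) of the day's readings, reading "first/fourth quartile" as
  data subsets; Q3 − Q1 is available as `mode="iqr"`.
* **ARV weights** are the inter-reading intervals; under the uniform
  15-min scheme they cancel, and the hand-worked examples in the tests
  pin the Σw·|ΔBP|/Σw normalization.
* **Spectral estimation**: beat values are interpolated onto a 10 Hz
  grid and band power is the integral of a Welch PSD (60-s Hann
  segments, 50% overlap, per-segment mean removal) over half-open
  (f_lo, f_hi] bands, so disjoint covers tile (0, Nyquist] exactly.
  Cubic-spline interpolation is the default because at rat beat rates
  (~5.3 Hz) the HF band (1.0–2.5 Hz) sits at a large fraction of the
  beat-sampling Nyquist, where linear interpolation attenuates band
  power to ~59% of truth; the spline recovers ~95% (the remaining ~5%
  is irreducible interpolation loss near Nyquist and is the dominant
  term in the HF recovery tolerance). `kind="linear"` remains available.
* **Foot detection**: zero-phase 4th-order Butterworth low-pass at
  40 Hz (the upstroke's bandwidth; zero-phase so no timing shift), a
  4-ms Savitzky–Golay derivative, maximum-dP/dt candidates gated by a
  refractory period of 0.6× the median cycle, and the
  intersecting-tangent construction with sub-sample output. Transit
  time is the median over pairs (each distal foot with the nearest
  preceding proximal foot within one period; non-positive delays
  dropped and counted). Because both traces pass through identical
  filters, shape biases cancel in the difference: noise-free recovery
  is exact to ~1e-11 relative, and at 5% amplitude noise the median
  error stays under 1%.
* **β index**: β = 2ρ·PWV²/DBP with ρ = 1.05 g/cm³ and DBP converted to
  dyn/cm². Published "beta index" values differ between groups by
  constant factors depending on convention; results must be read with
  the convention string carried in the report manifest.
* **MBP** uses DBP + PP/3, which reproduces published telemetric MBP
  values to the printed precision.
* **ANOVA + Fisher protected LSD**: textbook sums of squares, pairwise
  t tests on the pooled within-group mean square and its df, performed
  only when the omnibus p < α; no further multiplicity correction, per
  the classical procedure. Weekly time-course points are tested per
  week independently.

## Numerical and degenerate-input policy

Degenerate inputs raise `ValueError` rather than returning silent
defaults: flat traces (no beats/upstrokes), schedules disjoint from
readings, fewer than two readings for ARV, empty day/night periods,
aliased HF injection (hf_freq ≥ half the beat rate), delays outside one
beat period, non-positive PWV inputs, groups of n < 2, and fully
identical ANOVA data (F = 0/0). Zero within-group variance with unequal
means reports F = ∞, p = 0. ka = ke in the PK model falls back to the
analytic t·e^(−kt) limit.

## Problem sizes

Recovery experiments use sizes at which Monte-Carlo error is well below
the asserted tolerances while the whole suite stays fast: 500 simulated
days for the ARV Gaussian identity, 50 replicates × 300 s for spectral
recovery, 100 noisy waveform replicates for PWV, 200 rats for day-effect
recovery, and 2000 null replicates (k = 3, n = 5, the study's shape) for
the type-I error of the protected procedure.

## Known limitations

The PD calibration targets group means, not individual-rat dose-response
heterogeneity (all rats in an arm share Emax/EC50). The continuous arm
re-uses the same epoch-noise SD as placebo, so treatment effects on
short-term variability enter only through the drug-effect waveform.
PWV is simulated as a pure delay plus damping — no wave reflection or
pressure-dependence of wave speed. The day-effect recovery test
identifies the between-day SD only after subtracting the known epoch
noise contribution; with unknown noise, a mixed model would be needed.
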