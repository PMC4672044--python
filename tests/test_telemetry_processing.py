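"""Beat detection, epoch averaging and daily aggregation."""

import numpy as np
import pytest

from bpvlab.design import StudyDesign
from bpvlab.simulate import pulse_template
from bpvlab.telemetry import (BeatSeries, daily_means, detect_beats,
                              epoch_average)


def make_wave(pp=41.0, dbp=167.0, hr=320.0, fs=1000.0, duration=60.0):
    t = np.arange(int(duration * fs)) / fs
    return pulse_template(t, 60.0 / hr, pp, dbp)


class TestDetectBeats:
    def test_beat_count_matches_rate(self):
        beats = detect_beats(make_wave(hr=320.0, duration=60.0), fs=1000.0)
        # first beat is dropped (no preceding diastole)
        assert abs(len(beats) - 320) <= 2

    def test_flat_trace_is_an_error(self):
        with pytest.raises(ValueError, match="no beats"):
            detect_beats(np.full(5000, 120.0), fs=1000.0)

    def test_recovers_systolic_and_diastolic_levels(self):
        """Noise-free template at the acute placebo pressures: per-beat
        SBP/DBP within 0.5 mmHg of 208/167."""
        beats = detect_beats(make_wave(pp=41.0, dbp=167.0), fs=1000.0)
        assert np.sqrt(np.mean((beats.sbp - 208.0) ** 2)) < 0.5
        assert np.sqrt(np.mean((beats.dbp - 167.0) ** 2)) < 0.5


class TestEpochAverage:
    def test_72h_stream_yields_288_epochs(self, design):
        t = np.arange(0, 72 * 3600, 10.0)     # one reading every 10 s
        out = epoch_average({"sbp": np.full(t.size, 120.0),
                             "dbp": np.full(t.size, 80.0)},
                            design, times_s=t)
        assert len(out) == 288
        assert np.all(~np.isnan(out.sbp))

    def test_24h_stream_yields_96_valid_epochs(self, design):
        t = np.arange(0, 24 * 3600, 10.0)
        out = epoch_average({"sbp": np.full(t.size, 120.0),
                             "dbp": np.full(t.size, 80.0)},
                            design, times_s=t)
        assert np.sum(~np.isnan(out.sbp)) == 96

    def test_constant_reading_gives_constant_epochs(self, design):
        t = np.arange(0, 72 * 3600, 5.0)
        out = epoch_average({"sbp": np.full(t.size, 120.0),
                             "dbp": np.full(t.size, 80.0)},
                            design, times_s=t)
        np.testing.assert_allclose(out.sbp, 120.0)

    def test_idempotent_on_schedule_aligned_input(self, design):
        rng = np.random.default_rng(0)
        ticks = np.arange(288) * 900.0
        sbp = 120 + 5 * rng.standard_normal(288)
        once = epoch_average({"sbp": sbp, "dbp": sbp - 40}, design,
                             times_s=ticks)
        twice = epoch_average({"sbp": once.sbp, "dbp": once.dbp}, design,
                              times_s=once.epoch_times_h * 3600.0)
        np.testing.assert_array_equal(once.sbp, twice.sbp)

    def test_disjoint_schedule_is_an_error(self, design):
        with pytest.raises(ValueError, match="overlap"):
            epoch_average({"sbp": np.array([120.0]), "dbp": np.array([80.0])},
                          design, times_s=np.array([-5000.0]))

    def test_gap_epochs_marked_missing_not_interpolated(self, design):
        t = np.arange(0, 72 * 3600, 10.0)
        keep = (t < 3600) | (t >= 2 * 3600)   # hour-long dropout
        out = epoch_average({"sbp": np.full(keep.sum(), 120.0),
                             "dbp": np.full(keep.sum(), 80.0)},
                            design, times_s=t[keep])
        assert np.isnan(out.sbp[4:8]).all()
        assert np.sum(np.isnan(out.sbp)) == 4

    def test_beats_input(self, design):
        times = np.arange(0.0, 72 * 3600.0, 0.2)
        beats = BeatSeries(times, np.full(times.size, 150.0),
                           np.full(times.size, 100.0))
        out = epoch_average(beats, design)
        assert len(out) == 288
        np.testing.assert_allclose(out.sbp, 150.0)
        np.testing.assert_allclose(out.hr[1:], 300.0)   # 0.2 s IBI


class TestDailyMeans:
    def test_three_days_of_96(self, design, model, placebo_pk):
        from bpvlab.simulate import simulate_epoch_series
        from bpvlab.design import default_pk_for_group, PLACEBO
        pk = default_pk_for_group(PLACEBO, design.treatment_weeks)
        w = simulate_epoch_series(design, model, pk, PLACEBO, 0)[0]
        days = daily_means(w)
        assert [d.day_index for d in days] == [1, 2, 3]
        assert all(d.n_epochs == 96 for d in days)

    def test_constant_epochs_give_constant_daily_means(self):
        from bpvlab.telemetry import TelemetryEpochSeries
        t = np.arange(288) * 0.25
        s = TelemetryEpochSeries(t, np.full(288, 140.0), np.full(288, 100.0),
                                 np.full(288, 320.0))
        days = daily_means(s)
        assert [d.sbp_daily_mean for d in days] == [140.0] * 3

    def test_inserted_day_pattern_returned_in_order(self):
        from bpvlab.telemetry import TelemetryEpochSeries
        t = np.arange(288) * 0.25
        sbp = np.repeat([150.0, 150.0, 156.0], 96)
        s = TelemetryEpochSeries(t, sbp, sbp - 40, np.full(288, 320.0))
        assert [d.sbp_daily_mean for d in daily_means(s)] == [150.0, 150.0, 156.0]

    def test_daily_mean_equals_mean_of_its_96_epochs(self, rng):
        from bpvlab.telemetry import TelemetryEpochSeries
        t = np.arange(288) * 0.25
        sbp = 140 + 10 * rng.standard_normal(288)
        s = TelemetryEpochSeries(t, sbp, sbp - 40, np.full(288, 320.0))
        days = daily_means(s)
        for k, d in enumerate(days):
            assert d.sbp_daily_mean == pytest.approx(
                np.mean(sbp[96 * k:96 * (k + 1)]), abs=1e-12)

    def test_strict_mode_rejects_incomplete_windows(self):
        from bpvlab.telemetry import TelemetryEpochSeries
        t = np.arange(10) * 0.25
        s = TelemetryEpochSeries(t, np.full(10, 140.0), np.full(10, 100.0),
                                 np.full(10, 320.0))
        with pytest.raises(ValueError, match="complete day"):
            daily_means(s, strict=True)
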