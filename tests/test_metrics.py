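"""Variability indices: hand-computed oracles and invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from bpvlab.metrics import (arv, day_to_day_cv, day_to_day_sd,
                            quartile_spread, sd_24h, weighted_sd_24h)


def arv_loop(values, intervals=None):
    """Independent brute-force ARV: explicit loop over consecutive pairs."""
    n = len(values)
    w = [1.0] * (n - 1) if intervals is None else list(intervals)
    num = sum(w[k - 1] * abs(values[k] - values[k - 1]) for k in range(1, n))
    return num / sum(w)


class TestARV:
    def test_constant_series_is_zero(self):
        assert arv(np.full(96, 120.0)) == 0.0

    def test_alternating_series(self):
        assert arv(np.array([100.0, 110.0, 100.0, 110.0])) == pytest.approx(10.0)

    @pytest.mark.parametrize("w,expected", [((1.0, 3.0), 10.0),
                                            ((1.0, 0.5), 10.0)])
    def test_weight_invariance_when_all_jumps_equal(self, w, expected):
        assert arv(np.array([100.0, 110.0, 100.0]),
                   np.array(w)) == pytest.approx(expected)

    def test_matches_brute_force_loop_on_random_series(self, rng):
        for _ in range(100):
            n = rng.integers(2, 51)
            v = rng.normal(120, 15, n)
            w = rng.uniform(0.5, 2.0, n - 1)
            assert arv(v, w) == pytest.approx(arv_loop(v, w), abs=1e-12)
            assert arv(v) == pytest.approx(arv_loop(v), abs=1e-12)

    def test_iid_gaussian_arv_is_two_sigma_over_root_pi(self, rng):
        """E|X - Y| for iid N(0, s^2) is 2s/sqrt(pi); the mean ARV over
        500 simulated 96-reading days lands within 5%."""
        sigma = 8.0
        vals = [arv(rng.normal(0.0, sigma, 96)) for _ in range(500)]
        expected = 2.0 * sigma / np.sqrt(np.pi)
        assert np.mean(vals) == pytest.approx(expected, rel=0.05)

    def test_gap_breaks_the_chain(self):
        v = np.array([100.0, np.nan, 200.0, 210.0])
        assert arv(v) == pytest.approx(10.0)

    def test_errors(self):
        with pytest.raises(ValueError):
            arv(np.array([1.0]))
        with pytest.raises(ValueError):
            arv(np.array([1.0, 2.0, 3.0]), np.array([1.0, -1.0]))

    @settings(deadline=None, max_examples=50)
    @given(v=arrays(float, st.integers(2, 60),
                    elements=st.floats(-100, 300, allow_nan=False)),
           shift=st.floats(-50, 50, allow_nan=False))
    def test_translation_invariant(self, v, shift):
        assert arv(v + shift) == pytest.approx(arv(v), abs=1e-9)


class TestSD24h:
    def test_identical_values_zero(self):
        assert sd_24h(np.full(96, 130.0)) == 0.0

    def test_two_level_day(self):
        v = np.concatenate([np.full(48, 110.0), np.full(48, 130.0)])
        assert sd_24h(v) == pytest.approx(10.052493799, abs=1e-6)

    def test_noise_recovery_over_replicates(self, rng):
        """SD of a 96-epoch day with pure sigma=8 noise concentrates on 8."""
        sds = [sd_24h(rng.normal(120, 8, 96)) for _ in range(200)]
        assert np.mean(sds) == pytest.approx(8.0, abs=1.5)

    def test_incomplete_day_rejected_in_strict_mode(self):
        with pytest.raises(ValueError, match="incomplete"):
            sd_24h(np.full(50, 120.0))
        assert sd_24h(np.full(50, 120.0), strict=False) == 0.0


class TestWeightedSD:
    def test_identical_day_and_night_zero(self):
        assert weighted_sd_24h(np.full(48, 120.0), np.full(48, 120.0)) == 0.0

    def test_equal_periods_plain_mean(self, rng):
        d = rng.normal(120, 5, 48)
        n = rng.normal(130, 9, 48)
        expected = (np.std(d, ddof=1) + np.std(n, ddof=1)) / 2.0
        assert weighted_sd_24h(d, n) == pytest.approx(expected)

    def test_duration_weighting(self):
        rng = np.random.default_rng(1)
        d = rng.normal(0, 1, 2000)
        n = rng.normal(0, 1, 2000)
        sd_d, sd_n = np.std(d, ddof=1), np.std(n, ddof=1)
        got = weighted_sd_24h(d, n, day_hours=16, night_hours=8)
        assert got == pytest.approx((16 * sd_d + 8 * sd_n) / 24)
        # spot check against the hand-evaluated 5/9 case
        assert (16 * 5 + 8 * 9) / 24 == pytest.approx(6.3333, abs=1e-4)

    def test_empty_period_rejected(self):
        with pytest.raises(ValueError):
            weighted_sd_24h(np.array([1.0]), np.full(48, 120.0))


class TestDayToDay:
    def test_constant_days(self):
        assert day_to_day_sd([140.0, 140.0, 140.0]) == 0.0
        assert day_to_day_cv([140.0, 140.0, 140.0]) == 0.0

    def test_hand_evaluated_window(self):
        days = [138.0, 141.0, 144.0]
        assert day_to_day_sd(days) == pytest.approx(3.0)
        assert day_to_day_cv(days) == pytest.approx(2.12766, abs=1e-4)

    def test_rebound_pattern_closed_form(self):
        """(m, m, m+delta) has SD exactly delta/sqrt(3)."""
        for delta in (1.0, 4.0, 9.5):
            assert day_to_day_sd([100.0, 100.0, 100.0 + delta]) == \
                pytest.approx(delta / np.sqrt(3.0), abs=1e-12)

    def test_too_few_days_rejected(self):
        with pytest.raises(ValueError):
            day_to_day_sd([140.0])


class TestQuartileSpread:
    def test_constant_day_zero(self):
        assert quartile_spread(np.full(96, 120.0)) == 0.0

    def test_arithmetic_series(self):
        v = np.arange(1.0, 97.0)
        assert quartile_spread(v) == pytest.approx(72.0)

    def test_two_level_day(self):
        v = np.concatenate([np.full(48, 110.0), np.full(48, 130.0)])
        assert quartile_spread(v) == pytest.approx(20.0)

    def test_iqr_mode(self):
        v = np.arange(1.0, 97.0)
        q1, q3 = np.percentile(v, [25, 75])
        assert quartile_spread(v, mode="iqr") == pytest.approx(q3 - q1)

    def test_non_negative_and_scales(self, rng):
        v = rng.normal(120, 10, 96)
        q = quartile_spread(v)
        assert q >= 0
        assert quartile_spread(2 * v) == pytest.approx(2 * q)


@settings(deadline=None, max_examples=30)
@given(v=arrays(float, 96, elements=st.floats(50, 250, allow_nan=False)),
       a=st.floats(0.5, 3.0), b=st.floats(-40, 40))
def test_indices_translation_and_scale_behaviour(v, a, b):
    """All indices are translation-invariant except CV; all scale linearly
    except CV, which is scale-invariant."""
    if np.std(v) < 1e-9:
        return
    for fn in (arv, sd_24h, quartile_spread):
        base = fn(v)
        assert fn(v + b) == pytest.approx(base, rel=1e-9, abs=1e-9)
        assert fn(a * v) == pytest.approx(a * base, rel=1e-9, abs=1e-9)
    days = [np.mean(v[:32]), np.mean(v[32:64]), np.mean(v[64:])]
    days_scaled = [a * d for d in days]
    assert day_to_day_cv(days_scaled) == pytest.approx(day_to_day_cv(days),
                                                       rel=1e-9)
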