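"""Event-triggered rise rates, permutation nulls, jackknife bands, fractions."""

import numpy as np
import pytest

from risetrack.coupling import (
    during_event_fraction,
    event_centered_rise_rate,
    jackknife_band,
    paired_fraction_test,
    permutation_null,
    window_fractions,
)
from risetrack.synthetic import poisson_times


class TestRateCurve:
    def test_no_rises_gives_zero_curve(self):
        c = event_centered_rise_rate(np.array([]), np.array([100.0, 500.0]))
        assert np.allclose(c.rate, 0.0)

    def test_zero_events_is_an_error(self):
        with pytest.raises(ValueError, match="events"):
            event_centered_rise_rate(np.array([1.0]), np.array([]))

    def test_rise_at_every_event_peaks_at_gaussian_maximum(self):
        events = np.arange(200.0, 5000.0, 300.0)  # far apart: no cross terms
        c = event_centered_rise_rate(events.copy(), events)
        i0 = np.argmin(np.abs(c.lags))
        assert c.lags[i0] == 0.0
        assert c.rate[i0] == pytest.approx(1.0 / np.sqrt(2 * np.pi), rel=1e-6)
        assert np.argmax(c.rate) == i0

    def test_independent_poisson_rises_give_flat_curve_at_rate(self):
        rng = np.random.default_rng(0)
        lam = 0.05
        curves = []
        for _ in range(100):
            rises = poisson_times(lam, 20000.0, rng)
            events = poisson_times(0.003, 20000.0, rng)
            curves.append(event_centered_rise_rate(rises, events).rate)
        curves = np.asarray(curves)
        mean_curve = curves.mean(axis=0)
        se = curves.std(axis=0, ddof=1) / np.sqrt(curves.shape[0])
        inner = np.abs(np.linspace(-60, 60, mean_curve.size)) < 55
        # stationarity: mean within 4 SE pointwise, unbiased on average
        assert np.all(np.abs(mean_curve[inner] - lam) <= 4 * se[inner])
        assert mean_curve[inner].mean() == pytest.approx(lam, abs=0.001)

    def test_curve_mass_matches_pair_count(self):
        rng = np.random.default_rng(1)
        rises = poisson_times(0.02, 10800.0, rng)
        events = poisson_times(0.004, 10800.0, rng)
        c = event_centered_rise_rate(rises, events, lag_dt_s=0.1)
        n_pairs = sum(
            np.sum(np.abs(rises - e) <= 60.0) for e in events
        )
        mass = np.trapezoid(c.rate, c.lags) * events.size
        assert mass == pytest.approx(n_pairs, rel=0.02)


class TestPermutationNull:
    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(2)
        rises = poisson_times(0.02, 10800.0, rng)
        events = poisson_times(0.004, 10800.0, rng)
        lo1, hi1, m1 = permutation_null(rises, events, n_perm=50, seed=9)
        lo2, hi2, m2 = permutation_null(rises, events, n_perm=50, seed=9)
        assert np.array_equal(lo1, lo2) and np.array_equal(hi1, hi2)

    def test_band_brackets_null_mean(self):
        rng = np.random.default_rng(3)
        rises = poisson_times(0.02, 10800.0, rng)
        events = poisson_times(0.004, 10800.0, rng)
        lo, hi, mean = permutation_null(rises, events, n_perm=200, seed=1)
        assert np.all(lo <= mean + 1e-12) and np.all(mean <= hi + 1e-12)

    def test_too_few_rises_rejected(self):
        with pytest.raises(ValueError):
            permutation_null(np.array([5.0]), np.array([100.0]))

    def test_planted_coupling_detected_before_event(self):
        # rises placed 0.7 s before one third of the events
        rng = np.random.default_rng(4)
        rises = np.sort(rng.uniform(0, 10800, 150))
        chosen = rises[rng.random(rises.size) < 0.3]
        events = np.sort(chosen + 0.7)
        c = event_centered_rise_rate(rises, events)
        lo, hi, _ = permutation_null(rises, events, n_perm=500, seed=5)
        pre = (c.lags >= -3.0) & (c.lags <= 0.0)
        far = np.abs(c.lags) > 30.0
        assert np.any(c.rate[pre] > hi[pre])
        assert np.mean(c.rate[far] > hi[far]) < 0.2


class TestJackknife:
    def _data(self, seed=6):
        rng = np.random.default_rng(seed)
        rises = poisson_times(0.02, 10800.0, rng)
        events = poisson_times(0.004, 10800.0, rng)
        return rises, events

    def test_band_contains_rescaled_point_estimate(self):
        rises, events = self._data()
        c = event_centered_rise_rate(rises, events)
        lo, hi = jackknife_band(rises, events, n_resample=300, seed=7)
        assert np.all(lo <= c.rate + 1e-9)
        assert np.all(c.rate <= hi + 1e-9)

    def test_duplicating_rises_narrows_the_band(self):
        rises, events = self._data()
        lo1, hi1 = jackknife_band(rises, events, n_resample=300, seed=8)
        doubled = np.sort(np.concatenate([rises, rises + 1e-4]))
        lo2, hi2 = jackknife_band(doubled, events, n_resample=300, seed=8)
        # doubling the rises doubles the curve itself, so compare band
        # widths per unit of rate mass: variance scaling must shrink it
        assert np.mean(hi2 - lo2) / 2.0 < np.mean(hi1 - lo1)

    def test_fixed_seed_reproducible(self):
        rises, events = self._data()
        b1 = jackknife_band(rises, events, n_resample=100, seed=9)
        b2 = jackknife_band(rises, events, n_resample=100, seed=9)
        assert np.array_equal(b1[0], b2[0])

    def test_too_few_rises_rejected(self):
        with pytest.raises(ValueError):
            jackknife_band(np.arange(5.0), np.array([100.0]))


class TestWindowFractions:
    def test_paper_style_time_fraction_for_36_contacts(self):
        _, tf = window_fractions(np.array([1.0]), np.arange(1, 37) * 250.0)
        assert tf == pytest.approx(36 * 5 / 10800)
        assert round(100 * tf, 1) == 1.7

    def test_all_rises_right_before_events_fraction_one(self):
        events = np.array([100.0, 500.0, 900.0])
        rises = events - 1.0
        rf, _ = window_fractions(rises, events)
        assert rf == 1.0

    def test_rise_exactly_at_onset_excluded(self):
        rf, _ = window_fractions(np.array([100.0]), np.array([100.0]))
        assert rf == 0.0

    def test_uniform_rises_match_time_fraction(self):
        rng = np.random.default_rng(10)
        events = np.sort(rng.uniform(100, 10700, 36))
        fracs = [
            window_fractions(rng.uniform(0, 10800, 400), events)[0]
            for _ in range(60)
        ]
        _, tf = window_fractions(np.array([1.0]), events)
        assert np.mean(fracs) == pytest.approx(tf, abs=0.004)

    def test_zero_rises_reported_missing(self):
        rf, tf = window_fractions(np.array([]), np.array([100.0]))
        assert np.isnan(rf) and tf > 0

    def test_union_correction_shrinks_overlapping_windows(self):
        events = np.array([100.0, 102.0])  # windows overlap by 3 s
        _, tf_mult = window_fractions(np.array([1.0]), events)
        _, tf_union = window_fractions(np.array([1.0]), events, union_correct=True)
        assert tf_union == pytest.approx(7 / 10800)
        assert tf_mult == pytest.approx(10 / 10800)


class TestDuringEventFraction:
    def test_all_rises_inside_chases(self):
        rf, _ = during_event_fraction(np.array([10.0, 11.0]), [(5.0, 20.0)])
        assert rf == 1.0

    def test_no_chases(self):
        assert during_event_fraction(np.array([10.0]), []) == (0.0, 0.0)

    def test_uniform_rises_match_chase_time_coverage(self):
        rng = np.random.default_rng(11)
        # chases covering 8.4% of the dark phase
        starts = np.arange(0, 10800, 120.0)
        chases = [(s, s + 10.08) for s in starts]
        fracs = [
            during_event_fraction(rng.uniform(0, 10800, 500), chases)[0]
            for _ in range(40)
        ]
        rf, tf = during_event_fraction(rng.uniform(0, 10800, 500), chases)
        assert tf == pytest.approx(0.084, abs=1e-6)
        assert np.mean(fracs) == pytest.approx(0.084, abs=0.005)


class TestPairedFractionTest:
    def test_identical_pairs_give_t0_p1(self):
        t, p = paired_fraction_test([(0.03, 0.03), (0.05, 0.05), (0.02, 0.02)])
        assert (t, p) == (0.0, 1.0)

    def test_constant_positive_difference_degenerates(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            t, p = paired_fraction_test([(0.05, 0.03), (0.06, 0.04)])
        assert np.isinf(t) and t > 0 and p == 0.0

    def test_matches_closed_form_on_five_pairs(self):
        pairs = [(0.036, 0.017), (0.03, 0.02), (0.05, 0.01), (0.02, 0.025), (0.04, 0.02)]
        t, p = paired_fraction_test(pairs)
        d = np.array([a - b for a, b in pairs])
        t_manual = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
        assert t == pytest.approx(t_manual, rel=1e-12)
        from scipy.stats import t as tdist

        p_manual = 2 * tdist.sf(abs(t_manual), d.size - 1)
        assert p == pytest.approx(p_manual, rel=1e-12)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            paired_fraction_test([(0.1, 0.2)])
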