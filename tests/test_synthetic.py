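"""Generator invariants: determinism, conservation, and the planted structure."""

import numpy as np
import pytest

from risetrack import synthetic
from risetrack.core import EodfTrace
from risetrack.synthetic import (
    CohortConfig,
    ElectrodeGrid,
    TrialConfig,
    baseline_at_temperature,
    generate_agonistic_events,
    generate_cohort,
    generate_eodf_traces,
    generate_raw_recording,
    generate_trial,
    merge_chase_intervals,
)


class TestTrialConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(duration_s=-1.0),
            dict(sample_dt_s=0.0),
            dict(dark_s=30000.0),
            dict(rise_size_range_hz=(3.0, 68.0)),
            dict(trigger_prob=1.5),
            dict(baseline_hz=(700.0, 700.0)),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TrialConfig(**kwargs)

    def test_sub_threshold_rise_sizes_named_in_error(self):
        with pytest.raises(ValueError, match="undetectable"):
            TrialConfig(rise_size_range_hz=(2.0, 10.0))


class TestEodfTraces:
    def test_no_rises_no_noise_flat_temp_gives_constant_baseline(self):
        cfg = TrialConfig(
            duration_s=3600.0, dark_s=1800.0, n_rises=(0, 0),
            noise_sd_hz=0.0, temp_start_c=25.0, temp_drop_c=0.0, seed=0,
        )
        (loser, winner), truth = generate_eodf_traces(cfg)
        assert truth.empty
        assert np.allclose(loser.freq, cfg.baseline_hz[0])
        assert np.allclose(winner.freq, cfg.baseline_hz[1])

    def test_identical_seed_gives_bit_identical_output(self):
        cfg = TrialConfig(n_rises=(10, 2), seed=1)
        (a1, b1), t1 = generate_eodf_traces(cfg)
        (a2, b2), t2 = generate_eodf_traces(TrialConfig(n_rises=(10, 2), seed=1))
        assert np.array_equal(a1.freq, a2.freq)
        assert np.array_equal(b1.freq, b2.freq)
        assert t1.equals(t2)

    def test_q10_temperature_model_endpoint(self):
        # a fish at 722.39 Hz at 25 C cooled to 24 C sits at ~700 Hz
        assert baseline_at_temperature(722.39, 24.0, 1.37) == pytest.approx(
            700.0, abs=0.01
        )
        cfg = TrialConfig(
            baseline_hz=(722.39, 800.0), temp_start_c=25.0, temp_drop_c=1.0,
            n_rises=(0, 0), noise_sd_hz=0.0, seed=0,
        )
        (loser, _), _ = generate_eodf_traces(cfg)
        assert loser.freq[0] == pytest.approx(722.39, abs=1e-6)
        assert loser.freq[-1] == pytest.approx(700.0, abs=0.01)

    def test_ground_truth_has_configured_rise_counts_inside_support(self):
        cfg = TrialConfig(n_rises=(25, 4), seed=3)
        (loser, winner), truth = generate_eodf_traces(cfg)
        assert (truth["fish_id"] == "loser").sum() == 25
        assert (truth["fish_id"] == "winner").sum() == 4
        assert truth["onset_s"].between(loser.times[0], loser.times[-1]).all()
        assert (truth["size_hz"] >= 5.0).all()


class TestAgonisticEvents:
    def test_no_triggers_no_background_is_empty(self):
        cfg = TrialConfig(
            n_rises=(10, 0), trigger_prob=0.0,
            background_contact_rate=0.0, background_chase_rate=0.0, seed=5,
        )
        _, truth = generate_eodf_traces(cfg)
        events, _ = generate_agonistic_events(truth, cfg)
        assert events == []

    def test_certain_triggering_yields_one_contact_per_rise_at_exact_lag(self):
        cfg = TrialConfig(
            n_rises=(10, 0), trigger_prob=1.0,
            background_contact_rate=0.0, background_chase_rate=0.0, seed=5,
        )
        _, truth = generate_eodf_traces(cfg)
        events, _ = generate_agonistic_events(truth, cfg)
        assert len(events) == 10
        rise_times = np.sort(truth["onset_s"].to_numpy())
        for e, r in zip(events, rise_times):
            assert e.kind == "contact"
            assert e.onset_s == pytest.approx(r + 0.7, abs=1e-9)

    def test_triggered_events_trace_back_to_exactly_one_rise(self, default_trial):
        triggered = [e for e in default_trial.events if e.triggered_by >= 0]
        assert triggered, "default trigger probability should produce events"
        idx = [e.triggered_by for e in triggered]
        assert len(set(idx)) == len(idx)
        loser = default_trial.true_rises.query("fish_id == 'loser'")
        onsets = np.sort(loser["onset_s"].to_numpy())
        for e in triggered:
            assert e.onset_s == pytest.approx(
                onsets[e.triggered_by] + default_trial.config.contact_lag_s
            )

    def test_all_events_in_dark_phase_and_chases_positive(self, default_trial):
        for e in default_trial.events:
            assert 0.0 <= e.onset_s < default_trial.config.dark_s
            if e.kind == "chase":
                assert e.duration_s > 0.0

    def test_overlapping_chases_merged(self):
        merged, n = merge_chase_intervals([(0, 5), (3, 8), (10, 12)])
        assert merged == [(0, 8), (10, 12)]
        assert n == 1


class TestRawRecording:
    def test_rejects_single_electrode(self):
        with pytest.raises(ValueError, match="2 electrodes"):
            ElectrodeGrid(np.array([[0.0, 0.0]]))

    def test_single_fish_tone_peaks_at_eodf_on_every_channel(self):
        from risetrack.tracking import compute_spectrogram

        t = np.arange(0, 3.0, 0.1)
        trace = EodfTrace("a", t, np.full(t.size, 700.0))
        grid = ElectrodeGrid.regular(nx=2, ny=2)
        rec = generate_raw_recording((trace,), grid, noise_sd=0.0, seed=0)
        spec = compute_spectrogram(rec.data, rec.rate_hz)
        band = spec.freqs < 1000.0
        for ch in range(grid.n):
            peak = spec.freqs[band][np.argmax(spec.power[ch, band, 0])]
            assert abs(peak - 700.0) <= spec.freqs[1] - spec.freqs[0]

    def test_channel_of_maximal_power_follows_fish_position(self):
        t = np.arange(0, 2.0, 0.1)
        trace = EodfTrace("a", t, np.full(t.size, 700.0))
        grid = ElectrodeGrid.regular(nx=3, ny=2)
        corners = grid.positions[[0, -1]]
        argmaxes = []
        for pos in corners:
            rec = generate_raw_recording(
                (trace,), grid, fish_positions=pos[None, :], noise_sd=0.0, seed=0
            )
            argmaxes.append(int(np.argmax(rec.data.var(axis=0))))
        assert argmaxes[0] != argmaxes[1]
        assert argmaxes == [0, grid.n - 1]


class TestCohort:
    def test_zero_coefficients_make_size_irrelevant(self):
        df = generate_cohort(CohortConfig(n_trials=1000, coef={"dsize": 0.0}, seed=1))
        larger_wins = np.mean(
            np.where(df.a_wins, df.size_a > df.size_b, df.size_b > df.size_a)
        )
        assert abs(larger_wins - 0.5) < 3 * 0.5 / np.sqrt(1000)

    def test_huge_size_coefficient_saturates_outcomes(self):
        df = generate_cohort(CohortConfig(n_trials=1000, coef={"dsize": 50.0}, seed=2))
        larger_wins = np.mean(
            np.where(df.a_wins, df.size_a > df.size_b, df.size_b > df.size_a)
        )
        assert larger_wins > 0.99

    def test_sex_specific_eodf_ranges(self):
        df = generate_cohort(CohortConfig(n_trials=200, seed=3))
        for side in ("a", "b"):
            male = df[f"sex_{side}"] == 1
            assert (df.loc[male, f"eodf_{side}"] > 740).all()
            assert (df.loc[~male, f"eodf_{side}"] < 740).all()

    def test_nonfinite_coefficients_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            CohortConfig(coef={"dsize": float("nan")})


def test_generate_trial_is_deterministic(default_trial):
    again = generate_trial(TrialConfig(seed=7))
    assert np.array_equal(again.traces[0].freq, default_trial.traces[0].freq)
    assert again.true_rises.equals(default_trial.true_rises)
    assert len(again.events) == len(default_trial.events)
    assert all(
        a.onset_s == b.onset_s and a.kind == b.kind
        for a, b in zip(again.events, default_trial.events)
    )
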