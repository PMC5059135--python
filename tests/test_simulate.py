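"""Synthetic-recording generators: reproducibility, rate structure,
manipulations, evoked and optogenetic trial structure."""

import numpy as np
import pytest

import spindleloop as sl


class TestWaveGenerator:
    def test_degenerate_parameters_give_homogeneous_poisson(self):
        # depth 0 and base == wave rate: plain Poisson at that rate
        params = sl.WaveGeneratorParams(
            base_rate_hz=10.0, wave_rate_hz=10.0, modulation_depth=0.0,
            duration_s=200.0, seed=1,
        )
        s = sl.generate_wave_recording(sl.P9_11, params)
        n = len(s.train("LGN"))
        expected = 10.0 * 200.0
        assert abs(n - expected) < 3 * np.sqrt(expected)

    def test_active_fraction_and_rate_contrast(self):
        params = sl.WaveGeneratorParams(duration_s=600.0, seed=5)
        s = sl.generate_wave_recording(sl.P9_11, params)
        periods = s.meta["active_periods"]
        frac = sum(b - a for a, b in periods) / 600.0
        assert 0.05 < frac < 0.5
        train = s.train("LGN")
        in_active = sum(
            np.searchsorted(train.times_s, b) - np.searchsorted(train.times_s, a)
            for a, b in periods
        )
        out_active = len(train) - in_active
        active_t = sum(b - a for a, b in periods)
        assert in_active / active_t > 10 * out_active / (600.0 - active_t)

    def test_retinal_silencing_reduces_count(self):
        params = sl.WaveGeneratorParams(duration_s=600.0, seed=9)
        base = sl.generate_wave_recording(sl.P9_11, params)
        manip = sl.ManipulationSpec(target="retina", residual_fraction=0.1)
        silenced = sl.generate_wave_recording(sl.P9_11, params, manip)
        assert len(silenced.train("LGN")) <= 0.3 * len(base.train("LGN"))

    def test_reproducibility_bit_identical(self):
        params = sl.WaveGeneratorParams(duration_s=60.0, seed=3)
        a = sl.generate_wave_recording(sl.P9_11, params)
        b = sl.generate_wave_recording(sl.P9_11, params)
        for ta, tb in zip(a.spike_trains, b.spike_trains):
            assert np.array_equal(ta.times_s, tb.times_s)
        assert a.meta["active_periods"] == b.meta["active_periods"]

    def test_spike_times_strictly_increasing_within_span(self, short_wave_session):
        for tr in short_wave_session.spike_trains:
            assert np.all(np.diff(tr.times_s) > 0)
            assert tr.times_s[0] >= 0 and tr.times_s[-1] <= tr.span_s[1]

    def test_rate_autocorrelation_peaks_at_spindle_period(self):
        # oracle: autocorrelation of the binned counts has a local max
        # within one bin of 1/spindle_freq
        params = sl.WaveGeneratorParams(duration_s=300.0, seed=13)
        s = sl.generate_wave_recording(sl.P9_11, params)
        x = sl.bin_spike_train(s.train("LGN"), bin_ms=5.0).counts.astype(float)
        x = x - x.mean()
        lags_full = np.correlate(x, x, mode="full")
        acf = lags_full[x.size - 1 :]
        period_bins = int(round(1.0 / sl.P9_11.spindle_freq_hz / 0.005))
        window = acf[period_bins - 3 : period_bins + 4]
        k = np.argmax(window) + period_bins - 3
        assert abs(k - period_bins) <= 1

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            sl.WaveGeneratorParams(duration_s=-1.0)
        with pytest.raises(ValueError):
            sl.ManipulationSpec(target="cerebellum")
        with pytest.raises(ValueError):
            sl.ManipulationSpec(residual_fraction=1.5)


class TestEvokedTrials:
    def test_stimulus_timestamps_follow_protocol(self):
        proto = sl.StimulusProtocol(kind="flash", inter_trial_s=30.0, n_trials=10)
        s = sl.generate_evoked_trials(sl.P9_11, proto, seed=1)
        onsets = [ev.onset_s for ev in s.stimuli_of("flash")]
        assert onsets == pytest.approx(list(np.arange(10) * 30.0))

    def test_mature_mode_has_reduced_secondary(self):
        proto = sl.StimulusProtocol(kind="flash", inter_trial_s=30.0, n_trials=20)
        s = sl.generate_evoked_trials(sl.P13_14, proto, seed=2)
        split = sl.split_primary_secondary(s)
        base = s.meta["baseline_hz"]
        primary_evoked = split.primary.rate_hz.mean() - base
        secondary_evoked = split.secondary.rate_hz.mean() - base
        assert secondary_evoked < 0.25 * primary_evoked

    def test_immature_mode_both_windows_above_baseline(self):
        proto = sl.StimulusProtocol(kind="flash", inter_trial_s=30.0, n_trials=20)
        s = sl.generate_evoked_trials(sl.P9_11, proto, seed=3)
        split = sl.split_primary_secondary(s)
        base = s.meta["baseline_hz"]
        assert split.primary.rate_hz.mean() > base
        assert split.secondary.rate_hz.mean() > base

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError):
            sl.StimulusProtocol(kind="flash", n_trials=0)

    def test_non_flash_protocol_rejected(self):
        proto = sl.StimulusProtocol(kind="opto_single", pulse_dur_ms=10, inter_trial_s=10, n_trials=5)
        with pytest.raises(ValueError):
            sl.generate_evoked_trials(sl.P9_11, proto, seed=0)


class TestOptoTrials:
    def test_full_reliability_every_trial_responds(self):
        profile = sl.P9_11.with_(opto_reliability=1.0)
        proto = sl.StimulusProtocol(
            kind="opto_single", pulse_dur_ms=10, inter_trial_s=5, n_trials=100
        )
        s = sl.generate_opto_trials(profile, proto, seed=4)
        assert all(p["responded"] for p in s.meta["pulse_log"])
        assert sl.response_reliability(s) == pytest.approx(100.0)

    def test_age_latency_difference_recovered(self):
        # young vs mature latency settings differ by 14.2 ms; the
        # generator's own event offsets reproduce that difference
        proto = sl.StimulusProtocol(
            kind="opto_single", pulse_dur_ms=10, inter_trial_s=5, n_trials=150
        )
        lat = {}
        for prof in (sl.P5_7.with_(opto_jitter_ms=1.0), sl.P13_14):
            s = sl.generate_opto_trials(prof, proto, seed=6)
            lats = [p["lgn_latency_ms"] for p in s.meta["pulse_log"] if p["responded"]]
            lat[prof.name] = np.mean(lats)
        assert lat["P5_7"] - lat["P13_14"] == pytest.approx(14.2, abs=2.0)

    def test_inhibition_mode_suppresses_post_window(self):
        proto = sl.StimulusProtocol(
            kind="opto_single", pulse_dur_ms=10, inter_trial_s=5, n_trials=200
        )
        s = sl.generate_opto_trials(sl.P13_14, proto, seed=7)
        psth = sl.compute_psth(s, "opto", window_s=(-0.1, 0.3))
        assert psth.window_mean_hz((0.1, 0.25)) < psth.baseline_mean_hz

    def test_train_pulse_overlap_rejected(self):
        with pytest.raises(ValueError):
            sl.StimulusProtocol(
                kind="opto_train", pulse_dur_ms=60.0, inter_trial_s=2,
                n_trials=5, train_freq_hz=20.0, train_n_pulses=5,
            )


class TestSpectrumPopulationFixture:
    def test_rows_normalized_and_band_effect_confined(self):
        freq = np.geomspace(2, 100, 60)
        rng = np.random.default_rng(0)
        a = sl.sample_spectrum_population(6, freq, rng)
        norm = (freq >= 2) & (freq <= 55)
        assert a[:, norm].mean(axis=1) == pytest.approx(np.ones(6), abs=1e-9)
        b = sl.sample_spectrum_population(
            200, freq, rng, band_hz=(20, 28), band_scale=0.6
        )
        in_band = (freq >= 20) & (freq <= 28)
        out_band = norm & ~in_band
        base = sl.sample_spectrum_population(200, freq, np.random.default_rng(1))
        assert b[:, out_band].mean() == pytest.approx(base[:, out_band].mean(), rel=0.05)
        assert b[:, in_band].mean() == pytest.approx(0.6 * base[:, in_band].mean(), rel=0.08)
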