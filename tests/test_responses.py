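"""Trial-aligned analysis: PSTH, onset latency, reliability, window
changes, primary/secondary split, entrainment."""

import numpy as np
import pytest

import spindleloop as sl
from spindleloop.responses import Psth


def step_psth(k, bin_ms=1.0, window=(-0.05, 0.1), lo=2.0, hi=100.0, n_trials=50):
    """PSTH with a clean step from `lo` to `hi` at post-stimulus bin k."""
    dt = bin_ms / 1000.0
    n = int(round((window[1] - window[0]) / dt))
    edges = window[0] + np.arange(n + 1) * dt
    centers = 0.5 * (edges[:-1] + edges[1:])
    rng = np.random.default_rng(0)
    rate = np.where(centers < k * dt, lo, hi) + rng.normal(0, 0.3, n)
    return Psth(edges, np.clip(rate, 0, None), n_trials, (window[0], 0.0), bin_ms)


class TestPsth:
    def test_constant_rate_train_flat_psth(self):
        rng = np.random.default_rng(1)
        rate = 30.0
        times = np.sort(rng.uniform(0, 300, rng.poisson(rate * 300)))
        times = np.unique(times)
        trains = [sl.SpikeTrain("LGN", 0, times, (0.0, 300.0))]
        stimuli = [sl.StimulusEvent("flash", t) for t in np.arange(5.0, 295.0, 10.0)]
        s = sl.RecordingSession(spike_trains=trains, stimuli=stimuli)
        psth = sl.compute_psth(s, "flash", bin_ms=10.0, window_s=(-0.1, 0.3))
        total_s = psth.n_trials * 0.4
        sigma = np.sqrt(rate / (psth.n_trials * 0.01))
        assert abs(psth.rate_hz.mean() - rate) < 3 * sigma / np.sqrt(psth.rate_hz.size)

    def test_volley_latency_recovered(self, opto_session_p9):
        psth = sl.compute_psth(opto_session_p9, "opto", window_s=(-0.05, 0.1))
        mode = psth.bin_centers_s[np.argmax(psth.rate_hz)] * 1000
        # volley spans latency..latency+30 ms; its mode lies inside
        assert 21.5 - 2 <= mode <= 21.5 + 30 + 2

    def test_counts_conserved(self, opto_session_p9):
        psth = sl.compute_psth(opto_session_p9, "opto", window_s=(-0.1, 0.3))
        total = psth.rate_hz.sum() * (psth.bin_ms / 1000.0) * psth.n_trials
        assert total == pytest.approx(psth.total_spikes)

    def test_zero_trials_rejected(self, short_wave_session):
        with pytest.raises(ValueError):
            sl.compute_psth(short_wave_session, "opto")


class TestOnsetLatency:
    def test_step_at_exact_bin(self):
        for k in (5, 17, 40):
            onset = sl.onset_latency(step_psth(k))
            assert onset.responded
            assert onset.latency_ms == pytest.approx(k + 0.5, abs=0.51)

    def test_flat_psth_no_response(self):
        rng = np.random.default_rng(2)
        dt = 1e-3
        edges = -0.05 + np.arange(151) * dt
        rate = np.clip(rng.normal(5.0, 0.5, 150), 0, None)
        psth = Psth(edges, rate, 50, (-0.05, 0.0), 1.0)
        assert not sl.onset_latency(psth).responded

    @pytest.mark.parametrize("lat_ms", [20.0, 21.5, 34.0])
    def test_generator_latency_recovered_within_2ms(self, lat_ms):
        profile = sl.P9_11.with_(opto_latency_ms=lat_ms, opto_reliability=1.0, opto_jitter_ms=0.5)
        proto = sl.StimulusProtocol(
            kind="opto_single", pulse_dur_ms=10, inter_trial_s=5, n_trials=100
        )
        s = sl.generate_opto_trials(profile, proto, seed=int(lat_ms * 10))
        psth = sl.compute_psth(s, "opto", window_s=(-0.1, 0.2))
        onset = sl.onset_latency(psth)
        assert onset.responded
        assert abs(onset.latency_ms - lat_ms) <= 2.0 + 1e-9

    def test_lgn_vc_delay_matches_generator_settings(self, opto_session_p9):
        d = sl.lgn_vc_onset_delay(opto_session_p9, align="opto")
        assert d["delay_ms"] == pytest.approx(18.0, abs=2.0)


class TestReliability:
    def test_perfect_reliability(self):
        profile = sl.P9_11.with_(opto_reliability=1.0)
        proto = sl.StimulusProtocol(
            kind="opto_single", pulse_dur_ms=10, inter_trial_s=5, n_trials=100
        )
        s = sl.generate_opto_trials(profile, proto, seed=3)
        assert sl.response_reliability(s) == pytest.approx(100.0)

    def test_matches_hand_count_on_fixed_seed(self, opto_session_p9):
        # the estimator is the empirical mean of Bernoulli trials: agree
        # exactly with a hand count over the same windows
        rel = sl.response_reliability(opto_session_p9)
        lgn = opto_session_p9.train("LGN").times_s
        vc = opto_session_p9.train("VC").times_s
        qual = hits = 0
        for ev in opto_session_p9.stimuli_of("opto"):
            t = ev.onset_s
            if np.any((vc > t) & (vc <= t + 0.030)):
                qual += 1
                if np.any((lgn > t + 0.001) & (lgn <= t + 0.100)):
                    hits += 1
        assert rel == pytest.approx(100.0 * hits / qual)

    def test_age_ordering(self):
        proto = sl.StimulusProtocol(
            kind="opto_single", pulse_dur_ms=10, inter_trial_s=5, n_trials=150
        )
        young = sl.response_reliability(sl.generate_opto_trials(sl.P5_7, proto, seed=4))
        old = sl.response_reliability(sl.generate_opto_trials(sl.P13_14, proto, seed=4))
        assert young < old


class TestWindowRateChange:
    def test_window_equal_baseline_is_zero(self, opto_session_p9):
        psth = sl.compute_psth(opto_session_p9, "opto", window_s=(-0.1, 0.3))
        assert sl.window_rate_change(psth, psth.baseline_window_s) == pytest.approx(0.0)

    def test_inhibition_mode_negative_late_window(self):
        proto = sl.StimulusProtocol(
            kind="opto_single", pulse_dur_ms=10, inter_trial_s=5, n_trials=200
        )
        s = sl.generate_opto_trials(sl.P13_14, proto, seed=5)
        psth = sl.compute_psth(s, "opto", window_s=(-0.1, 0.3))
        assert sl.window_rate_change(psth, (0.1, 0.25)) < 0

    def test_no_inhibition_not_systematically_negative(self):
        proto = sl.StimulusProtocol(
            kind="opto_single", pulse_dur_ms=10, inter_trial_s=5, n_trials=100
        )
        changes = []
        for seed in range(10):
            s = sl.generate_opto_trials(sl.P9_11, proto, seed=seed)
            psth = sl.compute_psth(s, "opto", window_s=(-0.1, 0.3))
            changes.append(sl.window_rate_change(psth, (0.1, 0.25)))
        assert np.mean(changes) > -20.0


class TestPrimarySecondary:
    def test_band_specific_spectra(self):
        proto = sl.StimulusProtocol(kind="flash", inter_trial_s=30.0, n_trials=20)
        s = sl.generate_evoked_trials(sl.P9_11, proto, seed=6)
        split = sl.split_primary_secondary(s)
        p_spec, s_spec = split.spectra()
        p_peak = sl.peak_frequency(p_spec, (8.0, 55.0))
        s_peak = sl.peak_frequency(s_spec, (8.0, 55.0))
        assert 30.0 <= p_peak.freq_hz <= 50.0  # early gamma
        assert 8.0 <= s_peak.freq_hz <= 30.0  # spindle-burst band

    def test_window_exceeding_trial_span_rejected(self):
        proto = sl.StimulusProtocol(kind="flash", inter_trial_s=30.0, n_trials=3)
        s = sl.generate_evoked_trials(sl.P9_11, proto, seed=7)
        windows = sl.ResponseWindows(secondary_s=(0.2, 120.0))
        with pytest.raises(ValueError):
            sl.split_primary_secondary(s, windows)


class TestEntrainment:
    def test_p9_11_entrains_at_20hz(self):
        proto = sl.StimulusProtocol(
            kind="opto_train", pulse_dur_ms=10, inter_trial_s=2, n_trials=50,
            train_freq_hz=20.0, train_n_pulses=5,
        )
        s = sl.generate_opto_trials(sl.P9_11, proto, seed=8)
        e = sl.entrainment_index(s)
        assert e.entrained
        assert abs(e.psth_peak_hz - 20.0) <= e.freq_resolution_hz + 1e-9

    def test_p13_14_inhibition_defeats_entrainment(self):
        proto = sl.StimulusProtocol(
            kind="opto_train", pulse_dur_ms=10, inter_trial_s=2, n_trials=50,
            train_freq_hz=20.0, train_n_pulses=5,
        )
        s = sl.generate_opto_trials(sl.P13_14, proto, seed=9)
        e = sl.entrainment_index(s)
        assert not e.entrained
        assert e.pulse_probabilities[2:].mean() < 0.5 * e.pulse_probabilities[0]

    def test_single_pulse_protocol_rejected(self, opto_session_p9):
        with pytest.raises(ValueError):
            sl.entrainment_index(opto_session_p9)
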