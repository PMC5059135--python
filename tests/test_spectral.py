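"""Spectral pipeline: autocorrelation MUA spectra, multitaper LFP
spectra, 1/f compensation, log resampling, normalization, peaks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spindleloop as sl
from spindleloop.session import LfpTrace
from spindleloop.spectral import (
    SpectralParams,
    SpectrumEstimate,
    Spectrogram,
    _multitaper_window_psd,
    mua_spectrogram,
)
from tests.conftest import log_grid_index


class TestMuaAutocorrSpectrum:
    def test_poisson_null_is_flat(self):
        # homogeneous Poisson: normalized autocorrelation spectrum has
        # no bin in 5-55 Hz above 3x the band median, across 20 seeds
        for seed in range(20):
            tr = sl.modulated_poisson_train(20.0, 23.0, 0.0, 60.0, seed=seed)
            spec = sl.mua_spectrum(sl.bin_spike_train(tr))
            band = (spec.freq_hz >= 5) & (spec.freq_hz <= 55)
            p = spec.power[band]
            assert p.max() < 3.0 * np.median(p)

    def test_modulation_frequency_recovered(self):
        tr = sl.modulated_poisson_train(20.0, 23.0, 0.8, 100.0, seed=3)
        spec = sl.mua_spectrum(sl.bin_spike_train(tr))
        pk = sl.peak_frequency(spec)
        grid = spec.freq_hz
        assert abs(log_grid_index(pk.freq_hz, grid) - log_grid_index(23.0, grid)) <= 1

    def test_amplitude_scaling_preserves_peak_location(self):
        tr = sl.modulated_poisson_train(20.0, 23.0, 0.8, 60.0, seed=4)
        counts = sl.bin_spike_train(tr).counts.astype(float)
        s_full = sl.mua_spectrum_autocorr(counts)
        s_half = sl.mua_spectrum_autocorr(counts / 2.0)
        assert np.argmax(s_full.power) == np.argmax(s_half.power)

    def test_all_zero_counts_flagged_empty(self):
        spec = sl.mua_spectrum_autocorr(np.zeros(5000))
        assert spec.empty
        assert not spec.power.any()

    def test_total_power_tracks_count_variance(self):
        # Parseval-style sanity on the uncompensated spectrum
        tr = sl.modulated_poisson_train(30.0, 23.0, 0.5, 60.0, seed=5)
        counts = sl.bin_spike_train(tr).counts.astype(float)
        spec = sl.mua_spectrum_autocorr(counts)
        m = 2 * round(1.0 * 1000) + 1
        total = (spec.power[0] + 2 * spec.power[1:].sum()) / m
        assert total == pytest.approx(counts.var(), rel=0.05)

    def test_event_restricted_estimate(self, short_wave_session):
        train = short_wave_session.train("LGN")
        counts = sl.bin_spike_train(train)
        segs = [
            (a, b) for a, b in short_wave_session.meta["active_periods"] if b - a > 1.5
        ]
        spec = sl.mua_spectrum(counts, segments_s=segs)
        pk = sl.peak_frequency(spec)
        grid = spec.freq_hz
        assert abs(
            log_grid_index(pk.freq_hz, grid) - log_grid_index(sl.P9_11.spindle_freq_hz, grid)
        ) <= 1


class TestMultitaper:
    def test_sinusoid_peak_at_its_frequency(self):
        fs = 1000.0
        t = np.arange(int(60 * fs)) / fs
        rng = np.random.default_rng(0)
        x = np.sin(2 * np.pi * 20.0 * t) + 0.1 * rng.standard_normal(t.size)
        spec = sl.lfp_multitaper_spectrum(LfpTrace(x, fs))
        assert spec.freq_hz[np.argmax(spec.power)] == pytest.approx(20.0, abs=0.5)

    def test_two_second_window_gives_half_hz_resolution(self):
        fs = 1000.0
        spec = sl.lfp_multitaper_spectrum(
            LfpTrace(np.random.default_rng(1).standard_normal(int(10 * fs)), fs)
        )
        assert spec.freq_hz[1] - spec.freq_hz[0] == pytest.approx(0.5)

    def test_white_noise_compensated_rises_linearly(self):
        # white noise is flat; multiplying by f tilts it proportionally
        fs = 1000.0
        x = np.random.default_rng(2).standard_normal(int(200 * fs))
        spec = sl.compensate_one_over_f(sl.lfp_multitaper_spectrum(LfpTrace(x, fs)))
        f = spec.freq_hz

        def band_mean(lo, hi):
            sel = (f >= lo) & (f <= hi)
            return spec.power[sel].mean()

        assert band_mean(40, 50) / band_mean(10, 20) == pytest.approx(3.0, rel=0.1)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            sl.lfp_multitaper_spectrum(LfpTrace(np.zeros(100), 1000.0))


class TestCompensation:
    def test_one_over_f_becomes_flat(self):
        f = np.arange(1.0, 101.0)
        s = SpectrumEstimate(f, 7.0 / f)
        out = sl.compensate_one_over_f(s)
        assert out.power == pytest.approx(np.full(100, 7.0))

    def test_zero_frequency_bin_maps_to_zero(self):
        s = SpectrumEstimate(np.array([0.0, 1.0]), np.array([5.0, 5.0]))
        assert sl.compensate_one_over_f(s).power[0] == 0.0

    def test_round_trip_identity(self):
        rng = np.random.default_rng(3)
        f = np.arange(1.0, 51.0)
        p = rng.uniform(0.1, 2.0, 50)
        s = SpectrumEstimate(f, p)
        back = sl.compensate_one_over_f(sl.compensate_one_over_f(s), inverse=True)
        assert back.power == pytest.approx(p)

    def test_double_application_rejected(self):
        s = sl.compensate_one_over_f(SpectrumEstimate(np.arange(1.0, 11.0), np.ones(10)))
        with pytest.raises(ValueError):
            sl.compensate_one_over_f(s)


class TestLogResample:
    def test_flat_stays_flat(self):
        f = np.arange(0.0, 201.0) * 0.5
        s = sl.log_resample_spectrum(SpectrumEstimate(f, np.full(f.size, 2.0)))
        assert s.power == pytest.approx(np.full(60, 2.0))

    def test_identity_on_native_grid(self):
        f = np.arange(1.0, 101.0)
        p = np.random.default_rng(4).uniform(0.5, 2.0, 100)
        s = sl.log_resample_spectrum(SpectrumEstimate(f, p), grid_hz=f)
        assert s.power == pytest.approx(p)

    def test_narrow_peak_maps_to_nearest_log_bin(self):
        f = np.arange(0.0, 500.5, 0.5)
        p = np.ones(f.size)
        p[np.argmin(np.abs(f - 23.0))] = 50.0
        s = sl.log_resample_spectrum(SpectrumEstimate(f, p))
        # oracle: dense interpolation in log-f
        dense = np.geomspace(2, 100, 50000)
        dense_p = np.interp(np.log(dense), np.log(f[1:]), p[1:])
        oracle_f = dense[np.argmax(dense_p)]
        assert abs(
            log_grid_index(s.freq_hz[np.argmax(s.power)], s.freq_hz)
            - log_grid_index(oracle_f, s.freq_hz)
        ) <= 1

    def test_grid_outside_native_range_rejected(self):
        s = SpectrumEstimate(np.arange(5.0, 50.0), np.ones(45))
        with pytest.raises(ValueError, match="outside native range"):
            sl.log_resample_spectrum(s)


class TestNormalization:
    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=1e-6, max_value=1e6), min_size=120, max_size=120
        )
    )
    def test_in_band_mean_is_one(self, powers):
        f = np.linspace(0.5, 60.0, 120)
        s = sl.normalize_spectrum(SpectrumEstimate(f, np.asarray(powers)))
        band = (f >= 2) & (f <= 55)
        assert s.power[band].mean() == pytest.approx(1.0, abs=1e-9)

    def test_scale_invariance(self):
        f = np.linspace(1, 60, 100)
        p = np.random.default_rng(5).uniform(0.1, 3.0, 100)
        a = sl.normalize_spectrum(SpectrumEstimate(f, p))
        b = sl.normalize_spectrum(SpectrumEstimate(f, 10.0 * p))
        assert a.power == pytest.approx(b.power)

    def test_constant_spectrum_becomes_ones(self):
        f = np.linspace(2, 55, 50)
        s = sl.normalize_spectrum(SpectrumEstimate(f, np.full(50, 3.3)))
        assert s.power == pytest.approx(np.ones(50))

    def test_idempotent(self):
        f = np.linspace(1, 60, 100)
        p = np.random.default_rng(6).uniform(0.1, 3.0, 100)
        once = sl.normalize_spectrum(SpectrumEstimate(f, p))
        twice = sl.normalize_spectrum(once)
        assert twice.power == pytest.approx(once.power)

    def test_zero_band_power_rejected(self):
        f = np.linspace(1, 60, 100)
        with pytest.raises(ValueError):
            sl.normalize_spectrum(SpectrumEstimate(f, np.zeros(100)))


class TestPeakFrequency:
    def test_injected_peak_recovered(self):
        tr = sl.modulated_poisson_train(20.0, 16.0, 0.8, 100.0, seed=7)
        spec = sl.mua_spectrum(sl.bin_spike_train(tr))
        pk = sl.peak_frequency(spec)
        assert abs(
            log_grid_index(pk.freq_hz, spec.freq_hz) - log_grid_index(16.0, spec.freq_hz)
        ) <= 1

    def test_tie_resolves_to_lower_frequency(self):
        f = np.linspace(5, 55, 101)
        p = np.ones(101)
        p[np.argmin(np.abs(f - 15))] = 4.0
        p[np.argmin(np.abs(f - 25))] = 4.0
        pk = sl.peak_frequency(SpectrumEstimate(f, p))
        assert pk.freq_hz == pytest.approx(15.0, abs=0.5)

    def test_flat_spectrum_flagged_low_confidence(self):
        f = np.linspace(5, 55, 101)
        pk = sl.peak_frequency(SpectrumEstimate(f, np.ones(101)))
        assert pk.low_confidence

    def test_empty_band_rejected(self):
        s = SpectrumEstimate(np.linspace(60, 100, 10), np.ones(10))
        with pytest.raises(ValueError):
            sl.peak_frequency(s, search_band_hz=(5, 55))


class TestSpectrogram:
    def test_stationary_modulation_gives_constant_ridge(self):
        tr = sl.modulated_poisson_train(30.0, 23.0, 0.8, 60.0, seed=8)
        sg = mua_spectrogram(sl.bin_spike_train(tr))
        band = (sg.freq_hz >= 5) & (sg.freq_hz <= 55)
        ridge = sg.freq_hz[band][np.argmax(sg.power[band], axis=0)]
        assert np.median(np.abs(ridge - 23.0)) <= 2.0

    def test_silent_epochs_give_near_zero_columns(self):
        counts = np.zeros(20000)
        counts[:4000] = np.random.default_rng(9).poisson(0.05, 4000)
        sg = mua_spectrogram(counts)
        active_col = sg.power[:, 0].sum()
        silent_col = sg.power[:, -1].sum()
        assert silent_col < 1e-6 * active_col

    def test_time_average_matches_mean_spectrum(self):
        # spectrogram columns averaged over time equal the multitaper
        # spectrum of the same smoothed rate trace
        from scipy.ndimage import gaussian_filter1d

        tr = sl.modulated_poisson_train(30.0, 23.0, 0.8, 20.0, seed=10)
        b = sl.bin_spike_train(tr)
        sg = mua_spectrogram(b)
        rate = gaussian_filter1d(b.counts.astype(float) * b.fs_hz, sigma=5.0)
        n = round(2.0 * 1000)
        n_win = rate.size // n
        freq, psd = _multitaper_window_psd(
            rate[: n_win * n].reshape(n_win, n), 1000.0, (3.0, 5)
        )
        assert sg.power.mean(axis=1) == pytest.approx(psd, rel=1e-9)
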