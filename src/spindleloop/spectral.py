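"""Spectral estimation for MUA and LFP.

Two estimation pathways, mirroring how each signal class is treated:

* **MUA** — the Fourier transform of the (biased, mean-subtracted)
  autocorrelation of the 1 ms-binned spike counts, Hann-tapered in lag to
  suppress truncation ripple. The autocorrelation spectrum of a
  homogeneous Poisson train is flat, so no 1/f compensation is applied on
  this pathway by default.
* **LFP** — multitaper (Slepian) spectra over fixed windows (2 s
  spontaneous / 0.3 s evoked, taper parameters [3 5]), averaged across
  windows; these carry the 1/f background and are compensated by
  multiplying power by frequency.

Both pathways then share the same post-processing: optional 1/f
compensation, resampling onto a geometric (log-spaced) frequency grid to
equalize representation of high and low frequencies, and normalization
by mean 2-55 Hz power.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import get_window
from scipy.signal.windows import dpss

from .preprocess import BinnedTrain
from .session import LfpTrace


@dataclass
class SpectralParams:
    """Parameters of the spectral pipeline.

    ``window_s`` is the multitaper window (2 s spontaneous, 0.3 s
    evoked); ``tapers`` the (time-bandwidth, n-taper) pair; ``max_lag_s``
    the autocorrelation support for the MUA pathway (1 s -> 0.5 Hz
    resolution); ``log_grid`` the geometric resampling grid
    ``(f_min, f_max, n_points)``; ``norm_band_hz`` the normalization
    band; ``smooth_alpha_ms`` the Gaussian rate-smoothing used only for
    spectrogram display.
    """

    window_s: float = 2.0
    tapers: tuple[float, int] = (3.0, 5)
    max_lag_s: float = 1.0
    comp_one_over_f: bool = False
    norm_band_hz: tuple[float, float] = (2.0, 55.0)
    log_grid: tuple[float, float, int] = (2.0, 100.0, 60)
    smooth_alpha_ms: float = 5.0

    def __post_init__(self) -> None:
        if self.window_s <= 0 or self.max_lag_s <= 0:
            raise ValueError("window_s and max_lag_s must be positive")
        lo, hi = self.norm_band_hz
        f0, f1, npts = self.log_grid
        if not (f0 <= lo < hi <= f1):
            raise ValueError("norm_band_hz must lie within the log grid")


# evoked responses use a 0.3 s window; the shorter autocorrelation lag
# limits native resolution to ~3.3 Hz, so the log grid starts at 4 Hz
EVOKED_PARAMS = SpectralParams(
    window_s=0.3, max_lag_s=0.15, norm_band_hz=(4.0, 55.0), log_grid=(4.0, 100.0, 50)
)


@dataclass
class SpectrumEstimate:
    """A power spectrum with provenance flags."""

    freq_hz: np.ndarray
    power: np.ndarray
    n_windows: int = 1
    compensated: bool = False
    log_resampled: bool = False
    normalized: bool = False
    source: str = "MUA"
    empty: bool = False

    def __post_init__(self) -> None:
        self.freq_hz = np.asarray(self.freq_hz, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freq_hz.shape != self.power.shape:
            raise ValueError("freq/power shape mismatch")
        if not self.empty and np.any(self.power < 0):
            raise ValueError("power must be nonnegative")


def _log_grid(params: SpectralParams) -> np.ndarray:
    f0, f1, n = params.log_grid
    return np.geomspace(f0, f1, int(n))


# --------------------------------------------------------------------------
# MUA pathway: autocorrelation spectrum
# --------------------------------------------------------------------------

def _biased_autocorr(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased autocovariance of ``x`` at lags 0..max_lag via FFT
    (divides by the full length N at every lag)."""
    n = x.size
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    X = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(X * np.conj(X), nfft)[: max_lag + 1] / n
    return acf


def mua_spectrum_autocorr(
    counts: BinnedTrain | np.ndarray,
    params: SpectralParams | None = None,
    fs_hz: float = 1000.0,
    segments_s: Optional[Sequence[tuple[float, float]]] = None,
) -> SpectrumEstimate:
    """Spectrum of binned MUA as the Fourier transform of its
    autocorrelation.

    The count series is mean subtracted; its biased autocorrelation is
    computed to ``params.max_lag_s``, Hann tapered in lag, and Fourier
    transformed. Negative values from the numerical transform are clipped
    at zero (warning above 1% of the peak). The result is on a linear
    grid; compensation / log resampling / normalization are separate
    steps.

    ``segments_s`` restricts estimation to within-segment spike pairs
    (e.g. detected events): the autocovariance numerator is accumulated
    per segment and divided by the total segment length.
    """
    params = params or SpectralParams()
    if isinstance(counts, BinnedTrain):
        fs_hz = counts.fs_hz
        x = counts.counts.astype(float)
    else:
        x = np.asarray(counts, dtype=float)
    max_lag = round(params.max_lag_s * fs_hz)
    if x.size < max_lag + 1:
        raise ValueError(f"count series ({x.size} bins) shorter than max lag ({max_lag} bins)")
    if not np.any(x):
        f = np.fft.rfftfreq(2 * max_lag + 1, d=1.0 / fs_hz)
        return SpectrumEstimate(f, np.zeros_like(f), source="MUA", empty=True)

    if segments_s is None:
        acf = _biased_autocorr(x - x.mean(), max_lag)
    else:
        segs = []
        for a, b in segments_s:
            i0, i1 = int(a * fs_hz), int(b * fs_hz)
            if i1 - i0 > max_lag:
                segs.append(x[i0:i1])
        if not segs:
            raise ValueError("no segment longer than the autocorrelation lag")
        mu = np.concatenate(segs).mean()
        total = sum(s.size for s in segs)
        num = np.zeros(max_lag + 1)
        for s in segs:
            num += _biased_autocorr(s - mu, max_lag) * s.size
        acf = num / total

    # symmetric extension, taper, transform (lag 0 at index 0 after ifftshift)
    m = 2 * max_lag + 1
    sym = np.concatenate((acf[::-1], acf[1:]))
    taper = get_window("hann", m, fftbins=False)
    spec = np.fft.rfft(np.fft.ifftshift(sym * taper)).real
    neg = -spec.min(initial=0.0)
    if neg > 0.01 * max(spec.max(initial=0.0), 1e-300):
        warnings.warn(
            f"autocorrelation spectrum has negative excursions ({neg:.3g}); clipping at 0",
            RuntimeWarning,
        )
    spec = np.clip(spec, 0.0, None)
    freq = np.fft.rfftfreq(m, d=1.0 / fs_hz)
    return SpectrumEstimate(freq, spec, n_windows=1, source="MUA")


# --------------------------------------------------------------------------
# LFP pathway: multitaper
# --------------------------------------------------------------------------

def _multitaper_window_psd(
    segments: np.ndarray, fs_hz: float, tapers: tuple[float, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Mean multitaper PSD over ``segments`` (n_windows, n_samples)."""
    nw, k = tapers
    n = segments.shape[1]
    wins = dpss(n, nw, Kmax=int(k))  # (k, n)
    seg = segments - segments.mean(axis=1, keepdims=True)
    tapered = seg[:, None, :] * wins[None, :, :]
    spec = np.abs(np.fft.rfft(tapered, axis=-1)) ** 2
    psd = spec.mean(axis=(0, 1)) / (fs_hz * n)
    freq = np.fft.rfftfreq(n, d=1.0 / fs_hz)
    return freq, psd


def lfp_multitaper_spectrum(
    trace: LfpTrace, params: SpectralParams | None = None
) -> SpectrumEstimate:
    """Slepian-tapered spectrum of an LFP trace, averaged over
    consecutive non-overlapping fixed windows."""
    params = params or SpectralParams()
    n = round(params.window_s * trace.fs_hz)
    n_win = trace.samples.size // n
    if n_win < 1:
        raise ValueError(
            f"trace ({trace.samples.size} samples) shorter than one "
            f"{params.window_s} s window at fs={trace.fs_hz}"
        )
    segs = trace.samples[: n_win * n].reshape(n_win, n)
    freq, psd = _multitaper_window_psd(segs, trace.fs_hz, params.tapers)
    return SpectrumEstimate(freq, psd, n_windows=n_win, source="LFP")


# --------------------------------------------------------------------------
# shared post-processing
# --------------------------------------------------------------------------

def compensate_one_over_f(s: SpectrumEstimate, inverse: bool = False) -> SpectrumEstimate:
    """Multiply power by frequency to counter the 1/f background
    (``inverse=True`` divides, undoing a previous compensation)."""
    if inverse:
        if not s.compensated:
            raise ValueError("spectrum is not compensated; nothing to invert")
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(s.freq_hz > 0, s.power / np.where(s.freq_hz > 0, s.freq_hz, 1.0), 0.0)
        return replace(s, power=p, compensated=False)
    if s.compensated:
        raise ValueError("spectrum already compensated; refusing double application")
    return replace(s, power=s.power * s.freq_hz, compensated=True)


def log_resample_spectrum(
    s: SpectrumEstimate, grid_hz: np.ndarray | None = None, params: SpectralParams | None = None
) -> SpectrumEstimate:
    """Resample power onto a geometric frequency grid (default 2-100 Hz,
    60 points) by linear interpolation in log-frequency."""
    params = params or SpectralParams()
    grid = _log_grid(params) if grid_hz is None else np.asarray(grid_hz, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    pos = s.freq_hz > 0
    fmin, fmax = s.freq_hz[pos].min(), s.freq_hz[pos].max()
    if grid[0] < fmin or grid[-1] > fmax:
        raise ValueError(
            f"grid [{grid[0]}, {grid[-1]}] Hz outside native range [{fmin:.3g}, {fmax:.3g}] Hz"
        )
    p = np.interp(np.log(grid), np.log(s.freq_hz[pos]), s.power[pos])
    return replace(s, freq_hz=grid, power=p, log_resampled=True)


def normalize_spectrum(
    s: SpectrumEstimate, band_hz: tuple[float, float] = (2.0, 55.0)
) -> SpectrumEstimate:
    """Divide power by its mean over ``band_hz``; the normalized spectrum
    has in-band mean exactly 1."""
    lo, hi = band_hz
    in_band = (s.freq_hz >= lo) & (s.freq_hz <= hi)
    if not np.any(in_band):
        raise ValueError(f"no frequency bins in normalization band {band_hz}")
    mean = s.power[in_band].mean()
    if mean <= 0:
        raise ValueError("zero power in normalization band")
    return replace(s, power=s.power / mean, normalized=True)


@dataclass
class PeakFrequency:
    """Peak of a (normalized) spectrum in a search band. ``low_confidence``
    flags near-flat spectra (max/median < 1.5 in band)."""

    freq_hz: float
    power: float
    peak_to_median: float
    low_confidence: bool


def peak_frequency(
    s: SpectrumEstimate, search_band_hz: tuple[float, float] = (5.0, 55.0)
) -> PeakFrequency:
    """Argmax of power within the search band; ties resolve to the lower
    frequency."""
    lo, hi = search_band_hz
    in_band = (s.freq_hz >= lo) & (s.freq_hz <= hi)
    if not np.any(in_band):
        raise ValueError(f"no frequency bins in search band {search_band_hz}")
    f, p = s.freq_hz[in_band], s.power[in_band]
    i = int(np.argmax(p))  # first maximum = lowest frequency on a sorted grid
    med = float(np.median(p))
    ratio = float(p[i] / med) if med > 0 else np.inf
    return PeakFrequency(
        freq_hz=float(f[i]), power=float(p[i]), peak_to_median=ratio,
        low_confidence=ratio < 1.5,
    )


# --------------------------------------------------------------------------
# convenience pipeline + spectrogram
# --------------------------------------------------------------------------

def mua_spectrum(
    counts: BinnedTrain | np.ndarray,
    params: SpectralParams | None = None,
    fs_hz: float = 1000.0,
    segments_s: Optional[Sequence[tuple[float, float]]] = None,
) -> SpectrumEstimate:
    """Full MUA pipeline: autocorrelation spectrum -> (optional 1/f
    compensation) -> log resampling -> 2-55 Hz normalization."""
    params = params or SpectralParams()
    s = mua_spectrum_autocorr(counts, params, fs_hz=fs_hz, segments_s=segments_s)
    if s.empty:
        return s
    if params.comp_one_over_f:
        s = compensate_one_over_f(s)
    s = log_resample_spectrum(s, params=params)
    return normalize_spectrum(s, params.norm_band_hz)


def lfp_spectrum(trace: LfpTrace, params: SpectralParams | None = None) -> SpectrumEstimate:
    """Full LFP pipeline: multitaper -> 1/f compensation -> log
    resampling -> normalization."""
    params = params or SpectralParams(comp_one_over_f=True)
    s = lfp_multitaper_spectrum(trace, params)
    if params.comp_one_over_f:
        s = compensate_one_over_f(s)
    s = log_resample_spectrum(s, params=params)
    return normalize_spectrum(s, params.norm_band_hz)


@dataclass
class Spectrogram:
    times_s: np.ndarray
    freq_hz: np.ndarray
    power: np.ndarray  # (n_freq, n_times)


def mua_spectrogram(
    counts: BinnedTrain | np.ndarray,
    params: SpectralParams | None = None,
    fs_hz: float = 1000.0,
    step_s: float | None = None,
) -> Spectrogram:
    """Time-frequency display of MUA rate modulation: the count series is
    Gaussian-smoothed (5 ms alpha) into a rate estimate and multitaper
    spectra are computed over sliding windows. Display/qualitative use."""
    params = params or SpectralParams()
    if isinstance(counts, BinnedTrain):
        fs_hz = counts.fs_hz
        x = counts.counts.astype(float)
    else:
        x = np.asarray(counts, dtype=float)
    n = round(params.window_s * fs_hz)
    if x.size < n:
        raise ValueError("count series shorter than one spectrogram window")
    rate = gaussian_filter1d(x * fs_hz, sigma=params.smooth_alpha_ms / 1000.0 * fs_hz)
    step = n if step_s is None else round(step_s * fs_hz)
    starts = np.arange(0, x.size - n + 1, step)
    segs = np.stack([rate[i : i + n] for i in starts])
    cols = []
    for seg in segs:
        freq, psd = _multitaper_window_psd(seg[None, :], fs_hz, params.tapers)
        cols.append(psd)
    power = np.stack(cols, axis=1)
    times = (starts + n / 2) / fs_hz
    return Spectrogram(times_s=times, freq_hz=freq, power=power)
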