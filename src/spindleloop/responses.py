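"""Trial-aligned response analysis: PSTHs, onset latency, reliability,
excitation/inhibition windows, two-phase visual responses, and 20 Hz
train entrainment.

Conventions: PSTH bins are half-open, rates in Hz, windows in seconds
relative to stimulus onset. The response criterion shared across
estimators is baseline mean + 3 baseline SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .session import RecordingSession, SpikeTrain
from .spectral import SpectralParams, SpectrumEstimate, mua_spectrum_autocorr, peak_frequency


@dataclass
class Psth:
    """Trial-averaged peri-stimulus time histogram."""

    bin_edges_s: np.ndarray  # relative to stimulus onset
    rate_hz: np.ndarray
    n_trials: int
    baseline_window_s: tuple[float, float]
    bin_ms: float
    total_spikes: int = 0

    @property
    def bin_centers_s(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_s[:-1] + self.bin_edges_s[1:])

    def window_mean_hz(self, window_s: tuple[float, float]) -> float:
        """Mean rate over a window [a, b) relative to onset."""
        a, b = window_s
        c = self.bin_centers_s
        sel = (c >= a) & (c < b)
        if not np.any(sel):
            raise ValueError(f"window {window_s} contains no PSTH bins")
        return float(self.rate_hz[sel].mean())

    @property
    def baseline_mean_hz(self) -> float:
        return self.window_mean_hz(self.baseline_window_s)


@dataclass
class ResponseWindows:
    """Analysis windows relative to stimulus onset (seconds).

    Optogenetic: excitation 1-100 ms, inhibition 100-250 ms. Visual:
    primary (early-gamma) 0-200 ms, secondary (spindle-burst)
    200-1000 ms.
    """

    excitation_s: tuple[float, float] = (0.001, 0.100)
    inhibition_s: tuple[float, float] = (0.100, 0.250)
    primary_s: tuple[float, float] = (0.0, 0.200)
    secondary_s: tuple[float, float] = (0.200, 1.000)

    def __post_init__(self) -> None:
        for name in ("excitation_s", "inhibition_s", "primary_s", "secondary_s"):
            a, b = getattr(self, name)
            if b <= a:
                raise ValueError(f"{name} window not ordered: {(a, b)}")
        if self.excitation_s[1] > self.inhibition_s[0] + 1e-12:
            raise ValueError("excitation and inhibition windows overlap")
        if self.primary_s[1] > self.secondary_s[0] + 1e-12:
            raise ValueError("primary and secondary windows overlap")


def _trial_spikes(
    session: RecordingSession,
    kind: str,
    window_s: tuple[float, float],
    region: str,
    channel: int | None,
) -> tuple[list[np.ndarray], list[float]]:
    """Per-trial spike times relative to onset, for trials whose full
    window lies inside the recording span."""
    stims = session.stimuli_of(kind)
    if not stims:
        raise ValueError(f"session has no {kind!r} stimuli")
    train = session.train(region, channel) if channel is not None else _pooled(session, region)
    t0, t1 = train.span_s
    rel, onsets = [], []
    for ev in stims:
        a, b = ev.onset_s + window_s[0], ev.onset_s + window_s[1]
        if a < t0 or b > t1:
            continue  # partial window: would bias the trial average
        i0 = np.searchsorted(train.times_s, a)
        i1 = np.searchsorted(train.times_s, b)
        rel.append(train.times_s[i0:i1] - ev.onset_s)
        onsets.append(ev.onset_s)
    if not rel:
        raise ValueError("no stimulus has a fully in-span analysis window")
    return rel, onsets


def _pooled(session: RecordingSession, region: str) -> SpikeTrain:
    trains = session.trains(region)
    if not trains:
        raise KeyError(f"no {region} trains in session")
    if len(trains) == 1:
        return trains[0]
    from .session import merge_trains

    return merge_trains(trains, region=region)


def compute_psth(
    session: RecordingSession,
    align: str,
    bin_ms: float = 1.0,
    window_s: tuple[float, float] = (-0.1, 0.3),
    baseline_window_s: Optional[tuple[float, float]] = None,
    region: str = "LGN",
    channel: int | None = None,
) -> Psth:
    """Trial-aligned spike-rate histogram around stimuli of one kind.

    Rate per bin = pooled counts / (n_trials * bin width). The baseline
    window defaults to the pre-stimulus part of ``window_s``.
    """
    if bin_ms <= 0:
        raise ValueError("bin_ms must be positive")
    rel, _ = _trial_spikes(session, align, window_s, region, channel)
    n_trials = len(rel)
    dt = bin_ms / 1000.0
    n_bins = int(round((window_s[1] - window_s[0]) / dt))
    edges = window_s[0] + np.arange(n_bins + 1) * dt
    counts = np.zeros(n_bins)
    for r in rel:
        c, _ = np.histogram(r, bins=edges)
        counts += c
    if baseline_window_s is None:
        baseline_window_s = (window_s[0], min(0.0, window_s[1]))
    return Psth(
        bin_edges_s=edges,
        rate_hz=counts / (n_trials * dt),
        n_trials=n_trials,
        baseline_window_s=baseline_window_s,
        bin_ms=bin_ms,
        total_spikes=int(counts.sum()),
    )


@dataclass
class OnsetLatency:
    """Result of PSTH onset detection. ``responded`` is False when no
    sustained crossing was found (an explicit no-response)."""

    latency_ms: float
    responded: bool
    low_confidence: bool
    threshold_hz: float


def onset_latency(
    psth: Psth,
    smooth_ms: float = 2.0,
    n_sd: float = 3.0,
    n_consecutive: int = 3,
    refine_ms: float = 5.0,
) -> OnsetLatency:
    """Response onset: first post-stimulus bin where the smoothed PSTH
    exceeds baseline mean + ``n_sd`` baseline SD for ``n_consecutive``
    bins.

    Because Gaussian smoothing leaks a strong volley backwards in time,
    the crossing is then refined on the *unsmoothed* PSTH: starting
    ``refine_ms`` before the smoothed crossing, the onset is the first
    raw bin that exceeds the threshold together with its successor
    (two consecutive raw bins, so isolated baseline spikes cannot pull
    the onset early).
    """
    c = psth.bin_centers_s
    base = (c >= psth.baseline_window_s[0]) & (c < psth.baseline_window_s[1])
    if not np.any(base):
        raise ValueError("baseline window contains no bins")
    b_mean = psth.rate_hz[base].mean()
    b_sd = psth.rate_hz[base].std()
    low_conf = b_sd < 1e-9
    thr = b_mean + n_sd * b_sd + (1e-9 if low_conf else 0.0)

    dt = psth.bin_ms / 1000.0
    smoothed = gaussian_filter1d(psth.rate_hz, sigma=max(smooth_ms / psth.bin_ms, 1e-9))
    post = np.flatnonzero((c >= 0) & (smoothed > thr))
    onset_idx = None
    run = 1
    for k in range(len(post)):
        if k and post[k] == post[k - 1] + 1:
            run += 1
        else:
            run = 1
        if run >= n_consecutive:
            onset_idx = post[k] - n_consecutive + 1
            break
    if onset_idx is None:
        return OnsetLatency(np.nan, responded=False, low_confidence=low_conf, threshold_hz=thr)

    back = max(int(round(refine_ms / psth.bin_ms)), 0)
    lo = max(onset_idx - back, 0)
    raw = psth.rate_hz
    for idx in range(lo, raw.size):
        last = idx + 1 >= raw.size
        if c[idx] >= 0 and raw[idx] > thr and (last or raw[idx + 1] > thr):
            onset_idx = idx
            break
    return OnsetLatency(
        latency_ms=float(c[onset_idx] * 1000.0),
        responded=True,
        low_confidence=low_conf,
        threshold_hz=thr,
    )


def lgn_vc_onset_delay(
    session: RecordingSession, align: str = "opto", bin_ms: float = 1.0, **kw
) -> dict:
    """Delay between LGN and VC response onsets on the population PSTH."""
    out = {}
    for region in ("VC", "LGN"):
        psth = compute_psth(session, align, bin_ms=bin_ms, region=region)
        out[region] = onset_latency(psth, **kw)
    delay = out["LGN"].latency_ms - out["VC"].latency_ms
    return {"delay_ms": delay, "LGN": out["LGN"], "VC": out["VC"]}


def response_reliability(
    session: RecordingSession,
    windows: ResponseWindows | None = None,
    align: str = "opto",
    vc_window_s: tuple[float, float] = (0.0, 0.030),
) -> float:
    """Percentage of trials in which cortical spiking produced a thalamic
    response: among trials with >= 1 VC spike in ``vc_window_s``, the
    fraction with >= 1 LGN spike in the excitation window."""
    windows = windows or ResponseWindows()
    exc = windows.excitation_s
    full = (min(vc_window_s[0], exc[0]), max(vc_window_s[1], exc[1]))
    vc_rel, onsets = _trial_spikes(session, align, full, "VC", None)
    lgn_rel, onsets2 = _trial_spikes(session, align, full, "LGN", None)
    if onsets != onsets2:
        raise ValueError("LGN and VC trials do not align")
    qualifying = 0
    hits = 0
    for vc, lgn in zip(vc_rel, lgn_rel):
        if np.any((vc > vc_window_s[0]) & (vc <= vc_window_s[1])):
            qualifying += 1
            if np.any((lgn > exc[0]) & (lgn <= exc[1])):
                hits += 1
    if qualifying == 0:
        raise ValueError("no trial with a cortical response; reliability undefined")
    return 100.0 * hits / qualifying


def window_rate_change(
    psth: Psth,
    window_s: tuple[float, float],
    baseline_window_s: Optional[tuple[float, float]] = None,
) -> float:
    """Percent spike-rate change in a post-stimulus window relative to
    baseline: 100 * (window mean - baseline mean) / baseline mean."""
    base = baseline_window_s or psth.baseline_window_s
    b = psth.window_mean_hz(base)
    if b <= 0:
        raise ValueError("zero baseline rate; percent change undefined")
    w = psth.window_mean_hz(window_s)
    return 100.0 * (w - b) / b


@dataclass
class PrimarySecondarySplit:
    """Primary/secondary visual-response split: sub-PSTHs plus the
    trial-summed 1 ms count series of each window (input for evoked
    spectral analysis)."""

    primary: Psth
    secondary: Psth
    primary_counts: np.ndarray
    secondary_counts: np.ndarray
    count_fs_hz: float = 1000.0

    def spectra(self, params: SpectralParams | None = None) -> tuple[SpectrumEstimate, SpectrumEstimate]:
        """Autocorrelation spectra of the two windows (0.3 s evoked
        window -> short-lag parameters)."""
        from .spectral import EVOKED_PARAMS, log_resample_spectrum, normalize_spectrum

        params = params or EVOKED_PARAMS
        out = []
        for x in (self.primary_counts, self.secondary_counts):
            s = mua_spectrum_autocorr(x, params, fs_hz=self.count_fs_hz)
            s = log_resample_spectrum(s, params=params)
            out.append(normalize_spectrum(s, params.norm_band_hz))
        return tuple(out)


def split_primary_secondary(
    session: RecordingSession,
    windows: ResponseWindows | None = None,
    region: str = "LGN",
    bin_ms: float = 1.0,
    align: str = "flash",
) -> PrimarySecondarySplit:
    """Slice flash trials into primary (early-gamma) and secondary
    (spindle-burst) windows for rate and spectral analysis."""
    windows = windows or ResponseWindows()
    full = (-0.1, windows.secondary_s[1])
    rel, _ = _trial_spikes(session, align, full, region, None)
    dt = bin_ms / 1000.0

    def sub(window: tuple[float, float]) -> tuple[Psth, np.ndarray]:
        n_bins = int(round((window[1] - window[0]) / dt))
        edges = window[0] + np.arange(n_bins + 1) * dt
        counts = np.zeros(n_bins)
        for r in rel:
            c, _ = np.histogram(r, bins=edges)
            counts += c
        psth = Psth(
            bin_edges_s=edges,
            rate_hz=counts / (len(rel) * dt),
            n_trials=len(rel),
            baseline_window_s=(full[0], 0.0),
            bin_ms=bin_ms,
            total_spikes=int(counts.sum()),
        )
        return psth, counts

    p_psth, p_counts = sub(windows.primary_s)
    s_psth, s_counts = sub(windows.secondary_s)
    return PrimarySecondarySplit(
        primary=p_psth,
        secondary=s_psth,
        primary_counts=p_counts,
        secondary_counts=s_counts,
        count_fs_hz=1.0 / dt,
    )


@dataclass
class EntrainmentResult:
    """Per-pulse response probabilities and the train-aligned PSTH
    spectrum peak. ``entrained`` requires the spectral peak within one
    bin of the train frequency AND mean pulse-3..n probability at least
    half of pulse 1's."""

    pulse_probabilities: np.ndarray
    psth_peak_hz: float
    train_freq_hz: float
    freq_resolution_hz: float
    entrained: bool


def entrainment_index(
    session: RecordingSession,
    windows: ResponseWindows | None = None,
    align: str = "opto_train",
) -> EntrainmentResult:
    """Entrainment of thalamic firing by a cortical pulse train."""
    stims = session.stimuli_of(align)
    if not stims:
        raise ValueError("session has no opto_train stimuli (non-train protocol?)")
    params0 = stims[0].params
    freq = params0.get("train_freq_hz")
    n_pulses = params0.get("train_n_pulses")
    if not freq or not n_pulses:
        raise ValueError("opto_train stimuli lack train_freq_hz/train_n_pulses")
    windows = windows or ResponseWindows()
    ipi = 1.0 / freq
    resp_win = (windows.excitation_s[0], min(windows.excitation_s[1], ipi))

    train_span = n_pulses * ipi
    full = (-0.1, train_span + 0.1)
    rel, _ = _trial_spikes(session, align, full, "LGN", None)
    probs = np.zeros(n_pulses)
    for r in rel:
        for j in range(n_pulses):
            a = j * ipi + resp_win[0]
            b = j * ipi + resp_win[1]
            if np.any((r > a) & (r <= b)):
                probs[j] += 1
    probs /= len(rel)

    # train-aligned PSTH spectrum; the window extends 100 ms past the
    # last pulse to capture its volley and sharpen frequency resolution
    dt = 1e-3
    n_bins = int(round((train_span + 0.1) / dt))
    edges = np.arange(n_bins + 1) * dt
    counts = np.zeros(n_bins)
    for r in rel:
        c, _ = np.histogram(r, bins=edges)
        counts += c
    x = counts - counts.mean()
    spec = np.abs(np.fft.rfft(x)) ** 2
    f = np.fft.rfftfreq(n_bins, d=dt)
    df = f[1] - f[0]
    band = (f >= 2.0) & (f <= 100.0)
    peak_hz = float(f[band][np.argmax(spec[band])])

    sustained = probs[2:].mean() >= 0.5 * probs[0] if probs[0] > 0 else False
    entrained = bool(abs(peak_hz - freq) <= df + 1e-9 and sustained)
    return EntrainmentResult(
        pulse_probabilities=probs,
        psth_peak_hz=peak_hz,
        train_freq_hz=float(freq),
        freq_resolution_hz=float(df),
        entrained=entrained,
    )
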