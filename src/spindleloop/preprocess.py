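"""MUA extraction, spike binning, and analysis-channel selection.

MUA is extracted by negative threshold crossing (-50 uV) of the 300 Hz -
9 kHz band-passed wideband trace, with the band's upper edge capped at
the Nyquist frequency for synthetic sampling rates. Filtering is
zero-phase (4th-order Butterworth applied forward-backward) so onset
measures carry no filter latency; a 1 ms refractory lockout prevents
double-counting multiphasic waveforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .session import LfpTrace, RecordingSession, SpikeTrain

DEFAULT_MUA_BAND_HZ = (300.0, 9000.0)
DEFAULT_MUA_THRESHOLD_UV = -50.0
REFRACTORY_S = 1e-3


def extract_mua(
    trace: LfpTrace,
    threshold_uv: float = DEFAULT_MUA_THRESHOLD_UV,
    band_hz: tuple[float, float] = DEFAULT_MUA_BAND_HZ,
    refractory_s: float = REFRACTORY_S,
) -> SpikeTrain:
    """Detect multi-unit spikes as negative-going threshold crossings of
    the band-passed trace. Returns spike times at the crossing sample."""
    if threshold_uv == 0:
        raise ValueError("threshold must be nonzero")
    threshold_uv = -abs(threshold_uv)  # detection is on the negative lobe
    lo, hi = band_hz
    nyq = trace.fs_hz / 2.0
    if lo >= nyq:
        raise ValueError(
            f"band low edge {lo} Hz is at or above Nyquist ({nyq} Hz) for fs={trace.fs_hz} Hz"
        )
    if hi >= nyq:
        hi = 0.95 * nyq  # cap at Nyquist for synthetic sampling rates
    sos = butter(4, [lo, hi], btype="bandpass", fs=trace.fs_hz, output="sos")
    x = sosfiltfilt(sos, trace.samples)

    below = x < threshold_uv
    crossings = np.flatnonzero(below[1:] & ~below[:-1]) + 1
    if crossings.size == 0:
        times = np.empty(0)
    else:
        lockout = refractory_s * trace.fs_hz
        kept = [crossings[0]]
        for c in crossings[1:]:
            if c - kept[-1] >= lockout:
                kept.append(c)
        times = np.asarray(kept) / trace.fs_hz
    return SpikeTrain(
        region=trace.region,
        channel=trace.channel,
        times_s=times,
        span_s=(0.0, trace.samples.size / trace.fs_hz),
    )


@dataclass
class BinnedTrain:
    """Fixed-bin spike counts over a train's span; bins are half-open
    ``[t, t + dt)`` from the span start."""

    counts: np.ndarray
    bin_s: float
    t0: float

    @property
    def fs_hz(self) -> float:
        return 1.0 / self.bin_s

    @property
    def times_s(self) -> np.ndarray:
        return self.t0 + (np.arange(self.counts.size) + 0.5) * self.bin_s


def bin_spike_train(train: SpikeTrain, bin_ms: float = 1.0) -> BinnedTrain:
    """Count spikes in fixed ``bin_ms`` bins over the recording span.

    The last (possibly partial) bin is included so that the counts always
    sum to the number of spikes.
    """
    if bin_ms <= 0:
        raise ValueError("bin_ms must be positive")
    dt = bin_ms / 1000.0
    t0, t1 = train.span_s
    n_bins = int(np.ceil((t1 - t0) / dt - 1e-12))
    n_bins = max(n_bins, 1)
    edges = t0 + np.arange(n_bins + 1) * dt
    edges[-1] = max(edges[-1], t1) + 1e-12  # half-open bins; keep span-end spikes
    counts, _ = np.histogram(train.times_s, bins=edges)
    return BinnedTrain(counts=counts.astype(np.int64), bin_s=dt, t0=t0)


@dataclass
class ChannelSelection:
    """Outcome of analysis-channel selection for one region. ``channel``
    is ``None`` when no channel met the criterion (an explicit
    no-selection, never a silent default)."""

    region: str
    channel: int | None
    mode: str
    detail: dict


def select_analysis_channel(
    session: RecordingSession,
    mode: str,
    region: str = "LGN",
    psth_bin_ms: float = 1.0,
) -> ChannelSelection:
    """Pick the analysis channel for a region.

    ``evoked_earliest`` — the channel whose trial-averaged PSTH to flash
    stimuli first exceeds its response criterion (baseline mean + 3 SD,
    shared with the onset-latency estimator); requires flash stimuli.

    ``spindle_strongest`` — the channel with the highest spike rate
    inside detected events (the criterion used before visual
    responsiveness, P5-7).
    """
    from .events import detect_events
    from .responses import compute_psth, onset_latency

    channels = sorted({t.channel for t in session.trains(region)})
    if not channels:
        raise ValueError(f"session has no {region} trains")

    if mode == "evoked_earliest":
        if not session.stimuli_of("flash"):
            raise ValueError("evoked_earliest selection requires flash stimuli")
        latencies: dict[int, float] = {}
        for ch in channels:
            psth = compute_psth(session, "flash", bin_ms=psth_bin_ms, region=region, channel=ch)
            onset = onset_latency(psth)
            if onset.responded:
                latencies[ch] = onset.latency_ms
        if not latencies:
            return ChannelSelection(region, None, mode, {"reason": "no responsive channel"})
        best = min(latencies, key=lambda ch: (latencies[ch], ch))
        return ChannelSelection(region, best, mode, {"latency_ms": latencies})
    elif mode == "spindle_strongest":
        rates: dict[int, float] = {}
        for ch in channels:
            train = session.train(region, ch)
            ev = detect_events(train)
            total = sum(b - a for a, b in ev.events)
            if total > 0:
                n_in = sum(
                    int(np.searchsorted(train.times_s, b, "right") - np.searchsorted(train.times_s, a))
                    for a, b in ev.events
                )
                rates[ch] = n_in / total
        if not rates:
            return ChannelSelection(region, None, mode, {"reason": "no channel with events"})
        best = max(rates, key=lambda ch: (rates[ch], -ch))
        return ChannelSelection(region, best, mode, {"in_event_rate_hz": rates})
    raise ValueError(f"unknown selection mode {mode!r}")
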