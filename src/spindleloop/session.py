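"""Core containers for extracellular recording sessions.

A session bundles per-channel spike trains (multi-unit activity, MUA),
optional local-field-potential (LFP) traces, and a list of stimulus events,
together with metadata describing the age group and any silencing
manipulation. All times are seconds from session start; spike-count bins
are half-open ``[t, t + dt)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

REGIONS = ("LGN", "VC", "other")


@dataclass
class SpikeTrain:
    """Ordered spike timestamps for one channel in one region.

    Parameters
    ----------
    region : str
        One of ``"LGN"``, ``"VC"``, ``"other"``.
    channel : int
        Channel (contact) index.
    times_s : ndarray
        Strictly ascending spike times in seconds.
    span_s : (float, float)
        Recording span ``(t0, t1)``; all spikes lie within it.
    """

    region: str
    channel: int
    times_s: np.ndarray
    span_s: tuple[float, float]

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}; expected one of {REGIONS}")
        self.times_s = np.asarray(self.times_s, dtype=float)
        t0, t1 = self.span_s
        if t1 <= t0:
            raise ValueError(f"empty span {self.span_s}")
        if self.times_s.size:
            if np.any(np.diff(self.times_s) <= 0):
                raise ValueError("spike times must be strictly ascending")
            if self.times_s[0] < t0 or self.times_s[-1] > t1:
                raise ValueError("spike times outside recording span")

    @property
    def duration_s(self) -> float:
        return self.span_s[1] - self.span_s[0]

    @property
    def rate_hz(self) -> float:
        """Mean firing rate over the span."""
        return self.times_s.size / self.duration_s

    def __len__(self) -> int:
        return int(self.times_s.size)


@dataclass
class LfpTrace:
    """A continuous voltage trace in microvolts at a fixed sampling rate."""

    samples: np.ndarray
    fs_hz: float
    channel: int = 0
    region: str = "VC"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("LFP samples must be finite")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs_hz


@dataclass
class StimulusEvent:
    """One stimulus occurrence: kind (``flash``, ``opto``, ``opto_train``), onset, free-form params."""

    kind: str
    onset_s: float
    params: dict = field(default_factory=dict)


@dataclass
class RecordingSession:
    """Multi-region spike trains + optional LFP + stimulus events + metadata."""

    spike_trains: list[SpikeTrain]
    lfp: Optional[list[LfpTrace]] = None
    stimuli: list[StimulusEvent] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        spans = {st.span_s for st in self.spike_trains}
        if len(spans) > 1:
            raise ValueError(f"spike trains have unequal spans: {spans}")
        if self.spike_trains:
            t0, t1 = self.span_s
            for ev in self.stimuli:
                if not (t0 <= ev.onset_s <= t1):
                    raise ValueError(f"stimulus at {ev.onset_s} s outside span {self.span_s}")

    @property
    def span_s(self) -> tuple[float, float]:
        if not self.spike_trains:
            raise ValueError("session has no spike trains")
        return self.spike_trains[0].span_s

    @property
    def duration_s(self) -> float:
        t0, t1 = self.span_s
        return t1 - t0

    def trains(self, region: str | None = None, channel: int | None = None) -> list[SpikeTrain]:
        out = self.spike_trains
        if region is not None:
            out = [t for t in out if t.region == region]
        if channel is not None:
            out = [t for t in out if t.channel == channel]
        return out

    def train(self, region: str, channel: int | None = None) -> SpikeTrain:
        """The unique train for a region (and channel, if given)."""
        matches = self.trains(region, channel)
        if not matches:
            raise KeyError(f"no spike train for region={region!r} channel={channel!r}")
        if len(matches) > 1:
            raise KeyError(
                f"{len(matches)} trains match region={region!r}; pass an explicit channel"
            )
        return matches[0]

    def stimuli_of(self, kind: str) -> list[StimulusEvent]:
        return [ev for ev in self.stimuli if ev.kind == kind]


def merge_trains(trains: Sequence[SpikeTrain], region: str = "other", channel: int = -1) -> SpikeTrain:
    """Pool several trains into one MUA train (times re-sorted)."""
    if not trains:
        raise ValueError("no trains to merge")
    span = trains[0].span_s
    times = np.sort(np.concatenate([t.times_s for t in trains]))
    # enforce strict ascent: perturbing exact ties by half a nanosecond
    if times.size > 1:
        dup = np.flatnonzero(np.diff(times) <= 0)
        for i in dup:
            times[i + 1] = np.nextafter(times[i], np.inf)
    return SpikeTrain(region=region, channel=channel, times_s=times, span_s=span)
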