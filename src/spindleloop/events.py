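"""Event segmentation of spike trains and continuity statistics.

An *event* is a maximal run of at least ``min_spikes`` consecutive spikes
in which every adjacent inter-spike interval is strictly below the
threshold (default 500 ms). *Continuity* is the fraction of recording
time contained in events; isolated spikes contribute nothing. Event
span is [first spike, last spike] with no padding, so a two-spike event's
duration equals its ISI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .session import SpikeTrain


@dataclass
class EventSet:
    """Detected activity events for one spike train."""

    events: list[tuple[float, float]]
    n_spikes: list[int]
    span_s: tuple[float, float]
    iei_threshold_s: float = 0.5
    min_spikes: int = 2
    source: str = ""

    def __post_init__(self) -> None:
        for (a, b), n in zip(self.events, self.n_spikes):
            if b < a:
                raise ValueError(f"event with stop < start: ({a}, {b})")
            if n < self.min_spikes:
                raise ValueError("event below min_spikes")
        starts = [a for a, _ in self.events]
        if starts != sorted(starts):
            raise ValueError("events must be ordered")

    @property
    def durations_s(self) -> np.ndarray:
        return np.asarray([b - a for a, b in self.events])

    @property
    def total_event_time_s(self) -> float:
        return float(self.durations_s.sum()) if self.events else 0.0

    def __len__(self) -> int:
        return len(self.events)


@dataclass
class ContinuityResult:
    continuity: float
    total_event_time_s: float
    span_s: float


def detect_events(
    train: SpikeTrain, iei_threshold_s: float = 0.5, min_spikes: int = 2
) -> EventSet:
    """Segment a spike train into events (>= ``min_spikes`` spikes with
    every adjacent ISI strictly < ``iei_threshold_s``).

    Ties at exactly the threshold break the run (strict reading of
    "intervals of less than 500 ms").
    """
    if iei_threshold_s <= 0:
        raise ValueError("iei_threshold_s must be positive")
    t = train.times_s
    events: list[tuple[float, float]] = []
    counts: list[int] = []
    if t.size:
        # runs of consecutive short ISIs
        short = np.diff(t) < iei_threshold_s
        breaks = np.flatnonzero(~short)
        starts = np.concatenate(([0], breaks + 1))
        stops = np.concatenate((breaks, [t.size - 1]))
        for i0, i1 in zip(starts, stops):
            n = int(i1 - i0 + 1)
            if n >= min_spikes:
                events.append((float(t[i0]), float(t[i1])))
                counts.append(n)
    return EventSet(
        events=events,
        n_spikes=counts,
        span_s=train.span_s,
        iei_threshold_s=iei_threshold_s,
        min_spikes=min_spikes,
        source=f"{train.region}/{train.channel}",
    )


def compute_continuity(events: EventSet) -> ContinuityResult:
    """Fraction of the recording span contained in events."""
    t0, t1 = events.span_s
    span = t1 - t0
    if span <= 0:
        raise ValueError("zero recording span")
    total = events.total_event_time_s
    return ContinuityResult(continuity=total / span, total_event_time_s=total, span_s=span)


@dataclass
class DurationDistribution:
    """Histogram + empirical CDF of event durations."""

    durations_s: np.ndarray
    edges_s: np.ndarray
    histogram: np.ndarray
    empty: bool = False

    def cdf(self, x) -> np.ndarray:
        """Empirical CDF evaluated at x (right-continuous)."""
        if self.empty:
            raise ValueError("empty duration distribution")
        d = np.sort(self.durations_s)
        return np.searchsorted(d, np.atleast_1d(x), side="right") / d.size


#: default histogram edges, with explicit >5 s and >10 s tail bins
DEFAULT_DURATION_EDGES_S = np.array([0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 10.0, np.inf])


def event_duration_distribution(
    events: EventSet, edges_s: np.ndarray | None = None
) -> DurationDistribution:
    """Histogram (on supplied edges) and empirical CDF of event durations."""
    edges = np.asarray(DEFAULT_DURATION_EDGES_S if edges_s is None else edges_s, dtype=float)
    d = events.durations_s
    hist, _ = np.histogram(d, bins=edges)
    return DurationDistribution(
        durations_s=d, edges_s=edges, histogram=hist, empty=d.size == 0
    )


def percent_change(pre_value: float, post_value: float) -> float:
    """Signed percent change, 100 * (post - pre) / pre. ``pre`` must be
    positive — a zero baseline makes the quantity undefined."""
    if pre_value <= 0:
        raise ValueError(f"percent change undefined for pre={pre_value}")
    return 100.0 * (post_value - pre_value) / pre_value
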