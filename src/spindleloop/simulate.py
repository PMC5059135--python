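"""Synthetic recordings of neonatal retinal-wave-driven thalamocortical activity.

The generators produce :class:`~spindleloop.session.RecordingSession` objects
with the statistical structure the analysis pipeline assumes:

* spontaneous activity as an inhomogeneous Poisson process whose rate
  alternates between a low inter-wave baseline and wave-driven active
  periods carrying spindle-band (8-30 Hz) sinusoidal rate modulation;
* silencing manipulations (retina, LGN or VC) that scale the relevant
  drive by a residual fraction from an onset time;
* visually evoked trials with a two-phase response (early-gamma primary,
  spindle-burst secondary);
* optogenetic cortical stimulation with age-dependent latency,
  reliability and post-stimulus inhibition.

All rates are evaluated on a 1 ms grid and spikes are drawn by thinning;
every generator takes a mandatory integer seed (or a Generator) and is
bit-reproducible. Each session's ``meta`` carries the generator's own
ground-truth log (active periods, per-pulse outcomes, component
amplitudes) so downstream estimators can be tested against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .profiles import AgeProfile
from .session import LfpTrace, RecordingSession, SpikeTrain, StimulusEvent

#: fraction of LGN firing attributable to corticothalamic feedback during
#: the wave period; silencing VC removes this share of the wave drive.
FEEDBACK_FRACTION = 0.8

#: rate grid resolution (analysis operates on 1 kHz-sampled signals)
RATE_FS_HZ = 1000.0


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------

@dataclass
class WaveGeneratorParams:
    """Parameters of the spontaneous (retinal-wave-driven) generator.

    ``base_rate_hz`` is the inter-wave firing rate; during active periods
    the rate is ``wave_rate_hz * (1 + modulation_depth * sin(2*pi*f*t + phi))``
    with ``f`` the age profile's spindle frequency and a random phase per
    period. ``wave_dur_s`` / ``cluster_dur_s`` describe single-wave
    substructure (0.5-2 s waves in clusters up to 10 s); the generator
    treats whole active periods as the unit and keeps these as metadata
    only — sub-wave structure is not modelled.
    """

    base_rate_hz: float = 0.5
    wave_rate_hz: float = 30.0
    modulation_depth: float = 0.8
    wave_dur_s: tuple[float, float] = (0.5, 2.0)
    cluster_dur_s: float = 10.0
    duration_s: float = 1200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_rate_hz < 0 or self.wave_rate_hz < 0:
            raise ValueError("rates must be nonnegative")
        if not 0.0 <= self.modulation_depth <= 1.0:
            raise ValueError("modulation_depth must lie in [0, 1]")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")


MANIPULATION_TARGETS = ("none", "retina", "lgn", "vc")


@dataclass
class ManipulationSpec:
    """Acute silencing manipulation: scale the target's drive by
    ``residual_fraction`` from ``onset_s`` onwards."""

    target: str = "none"
    residual_fraction: float = 1.0
    onset_s: float = 0.0

    def __post_init__(self) -> None:
        if self.target not in MANIPULATION_TARGETS:
            raise ValueError(
                f"unknown manipulation target {self.target!r}; expected one of {MANIPULATION_TARGETS}"
            )
        if not 0.0 <= self.residual_fraction <= 1.0:
            raise ValueError("residual_fraction must lie in [0, 1]")


@dataclass
class StimulusProtocol:
    """A stimulation protocol: whole-field flashes, single optogenetic
    pulses, or pulse trains.

    Defaults follow the experimental protocols: 100 ms flashes every
    30 s; 10 ms light pulses; trains of five 10 ms pulses at 20 Hz.
    """

    kind: str = "flash"
    pulse_dur_ms: float = 100.0
    inter_trial_s: float = 30.0
    n_trials: int = 30
    train_freq_hz: Optional[float] = None
    train_n_pulses: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in ("flash", "opto_single", "opto_train"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        is_train = self.kind == "opto_train"
        has_train = self.train_freq_hz is not None and self.train_n_pulses is not None
        if is_train and not has_train:
            raise ValueError("opto_train requires train_freq_hz and train_n_pulses")
        if not is_train and (self.train_freq_hz is not None or self.train_n_pulses is not None):
            raise ValueError("train parameters are only valid for kind='opto_train'")
        if is_train and self.train_freq_hz * self.pulse_dur_ms / 1000.0 >= 1.0:
            raise ValueError(
                f"pulse duration {self.pulse_dur_ms} ms incompatible with "
                f"{self.train_freq_hz} Hz train (pulses overlap)"
            )


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# --------------------------------------------------------------------------
# Poisson machinery
# --------------------------------------------------------------------------

def spikes_from_rate(
    rate_hz: np.ndarray, rng: np.random.Generator, fs_hz: float = RATE_FS_HZ, t0: float = 0.0
) -> np.ndarray:
    """Draw an inhomogeneous Poisson spike train by thinning a rate trace.

    ``rate_hz`` is the piecewise-constant intensity on a ``1/fs_hz`` grid.
    Candidate events are drawn from a homogeneous process at the maximum
    rate and accepted with probability ``rate(t)/rate_max``. Returns
    strictly increasing times in seconds.
    """
    rate_hz = np.asarray(rate_hz, dtype=float)
    if np.any(rate_hz < 0):
        raise ValueError("rate must be nonnegative")
    rmax = float(rate_hz.max(initial=0.0))
    duration = rate_hz.size / fs_hz
    if rmax == 0.0:
        return np.empty(0)
    n_cand = rng.poisson(rmax * duration)
    cand = np.sort(rng.uniform(0.0, duration, size=n_cand))
    idx = np.minimum((cand * fs_hz).astype(np.intp), rate_hz.size - 1)
    keep = rng.uniform(0.0, 1.0, size=n_cand) < rate_hz[idx] / rmax
    times = cand[keep] + t0
    # enforce strict ascent (exact float ties are essentially impossible
    # but would violate the container invariant)
    if times.size > 1:
        for i in np.flatnonzero(np.diff(times) <= 0):
            times[i + 1] = np.nextafter(times[i], np.inf)
    return times


def modulated_poisson_train(
    rate_hz: float,
    f_mod_hz: float,
    depth: float,
    duration_s: float,
    seed,
    phase: float = 0.0,
    fs_hz: float = RATE_FS_HZ,
) -> SpikeTrain:
    """A sinusoidally rate-modulated Poisson train: the elementary
    oscillating-MUA test signal.

    rate(t) = rate_hz * (1 + depth * sin(2*pi*f_mod_hz*t + phase))
    """
    if not 0.0 <= depth <= 1.0:
        raise ValueError("depth must lie in [0, 1]")
    rng = _as_rng(seed)
    t = np.arange(round(duration_s * fs_hz)) / fs_hz
    rate = rate_hz * (1.0 + depth * np.sin(2.0 * np.pi * f_mod_hz * t + phase))
    times = spikes_from_rate(rate, rng, fs_hz)
    return SpikeTrain(region="LGN", channel=0, times_s=times, span_s=(0.0, duration_s))


# --------------------------------------------------------------------------
# spontaneous wave-driven activity
# --------------------------------------------------------------------------

def _draw_active_periods(
    age: AgeProfile, duration_s: float, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Alternate silent/active periods with uniform durations from the profile."""
    periods = []
    t = rng.uniform(*age.silent_dur_s)  # start in silence
    while t < duration_s:
        dur = rng.uniform(*age.active_dur_s)
        stop = min(t + dur, duration_s)
        periods.append((t, stop))
        t = stop + rng.uniform(*age.silent_dur_s)
    return periods


def generate_wave_recording(
    age: AgeProfile,
    params: WaveGeneratorParams,
    manip: ManipulationSpec | None = None,
    make_lfp: bool = False,
) -> RecordingSession:
    """Simulate spontaneous LGN and VC multi-unit activity during the
    retinal-wave period, optionally under an acute silencing manipulation.

    The LGN rate alternates between ``base_rate_hz`` (silence) and a
    spindle-modulated wave rate (active); VC follows the same active
    structure (cortical activity tracks the macro-patterning of retinal
    waves). Manipulations scale the relevant drive by
    ``residual_fraction`` from ``onset_s``:

    * ``retina`` — the wave drive of both regions;
    * ``lgn``    — thalamic output and therefore cortical drive too;
    * ``vc``     — cortical firing, and the feedback share
      (:data:`FEEDBACK_FRACTION`) of the LGN wave drive; at ages where
      cortex accelerates the rhythm, the modulation frequency drops to
      the profile's no-feedback frequency.

    The session ``meta`` records the active-period log and all generator
    settings.
    """
    manip = manip or ManipulationSpec()
    if params.duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = _as_rng(params.seed)
    n = round(params.duration_s * RATE_FS_HZ)
    t = np.arange(n) / RATE_FS_HZ

    periods = _draw_active_periods(age, params.duration_s, rng)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=len(periods))

    manip_scale = np.ones(n)
    if manip.target != "none":
        manip_scale[t >= manip.onset_s] = manip.residual_fraction

    # per-region wave drive envelopes
    lgn_wave = np.zeros(n)
    vc_wave = np.zeros(n)
    freq = age.spindle_freq_hz
    vc_freq = age.spindle_freq_hz
    lgn_wave_gain = np.ones(n)
    if manip.target == "vc":
        # silencing cortex removes the feedback share of the LGN wave drive
        # and (where applicable) slows the modulation rhythm
        after = t >= manip.onset_s
        lgn_wave_gain[after] = 1.0 - FEEDBACK_FRACTION * (1.0 - manip.residual_fraction)
        if age.spindle_freq_no_feedback_hz is not None:
            freq_after = age.spindle_freq_no_feedback_hz
        else:
            freq_after = freq
    else:
        freq_after = freq

    for (start, stop), phi in zip(periods, phases):
        sl = slice(int(start * RATE_FS_HZ), int(stop * RATE_FS_HZ))
        tt = t[sl] - start
        in_manip = manip.target == "vc" and start >= manip.onset_s
        f_lgn = freq_after if in_manip else freq
        lgn_wave[sl] = params.wave_rate_hz * (
            1.0 + params.modulation_depth * np.sin(2.0 * np.pi * f_lgn * tt + phi)
        )
        vc_wave[sl] = params.wave_rate_hz * (
            1.0 + params.modulation_depth * np.sin(2.0 * np.pi * vc_freq * tt + phi)
        )

    # the rate *alternates* between the baseline (silence) and the wave
    # drive (active periods); manipulations scale the relevant drive
    active = lgn_wave > 0
    lgn_drive = lgn_wave * lgn_wave_gain
    vc_drive = vc_wave.copy()
    if manip.target == "retina":
        lgn_drive = lgn_wave * manip_scale
        vc_drive = vc_wave * manip_scale
    elif manip.target == "lgn":
        lgn_drive = lgn_wave * manip_scale
        vc_drive = vc_wave * manip_scale
    lgn_rate = np.where(active, lgn_drive, params.base_rate_hz)
    vc_rate = np.where(active, vc_drive, params.base_rate_hz)
    if manip.target == "lgn":
        lgn_rate = lgn_rate * manip_scale  # thalamic output itself is silenced
    elif manip.target == "vc":
        vc_rate = vc_rate * manip_scale

    span = (0.0, params.duration_s)
    lgn_times = spikes_from_rate(lgn_rate, rng)
    vc_times = spikes_from_rate(vc_rate, rng)
    trains = [
        SpikeTrain("LGN", 0, lgn_times, span),
        SpikeTrain("VC", 0, vc_times, span),
    ]

    lfp = None
    if make_lfp:
        lfp = [synthesize_lfp(periods, params.duration_s, vc_freq, rng)]

    meta = {
        "kind": "spontaneous",
        "age": age.name,
        "seed": params.seed,
        "manipulation": {
            "target": manip.target,
            "residual_fraction": manip.residual_fraction,
            "onset_s": manip.onset_s,
        },
        "generator": {
            "base_rate_hz": params.base_rate_hz,
            "wave_rate_hz": params.wave_rate_hz,
            "modulation_depth": params.modulation_depth,
            "duration_s": params.duration_s,
            "spindle_freq_hz": freq,
            "spindle_freq_after_manip_hz": freq_after,
        },
        "active_periods": [(float(a), float(b)) for a, b in periods],
    }
    return RecordingSession(spike_trains=trains, lfp=lfp, meta=meta)


def synthesize_lfp(
    active_periods: Sequence[tuple[float, float]],
    duration_s: float,
    spindle_freq_hz: float,
    rng: np.random.Generator,
    fs_hz: float = RATE_FS_HZ,
    noise_uv: float = 20.0,
    spindle_uv: float = 120.0,
) -> LfpTrace:
    """Band-limited noise plus a spindle-band oscillation during active
    periods — the minimal LFP consistent with the analysis assumptions."""
    n = round(duration_s * fs_hz)
    t = np.arange(n) / fs_hz
    # brown-ish background: integrated white noise, high-passed by differencing scale
    noise = gaussian_filter1d(rng.standard_normal(n), sigma=3.0) * noise_uv
    x = noise.copy()
    for start, stop in active_periods:
        sl = slice(int(start * fs_hz), int(stop * fs_hz))
        tt = t[sl] - start
        env = np.sin(np.pi * np.minimum(tt / max(stop - start, 1e-9), 1.0)) ** 2
        x[sl] += spindle_uv * env * np.sin(2.0 * np.pi * spindle_freq_hz * tt)
    return LfpTrace(samples=x, fs_hz=fs_hz, channel=0, region="VC")


# --------------------------------------------------------------------------
# evoked (flash) trials
# --------------------------------------------------------------------------

#: early-gamma centre frequency of the primary visual response
EGO_FREQ_HZ = 40.0


def generate_evoked_trials(
    age: AgeProfile,
    protocol: StimulusProtocol,
    seed: int = 0,
    n_channels: int = 1,
    channel_stagger_ms: float = 0.0,
    baseline_hz: float = 2.0,
) -> RecordingSession:
    """Simulate visually evoked trials (whole-field flash).

    Each trial's LGN rate is baseline + a primary component (early-gamma,
    30-50 Hz band, 0-200 ms) + a secondary component (spindle-band
    oscillation, 200-1000 ms). In ``P13_14`` mode the primary is a brief
    non-oscillatory transient and the secondary is greatly reduced —
    the mature, two-phase-less response. Stimulus onsets are at
    ``0, inter_trial_s, 2*inter_trial_s, ...``.

    ``n_channels`` > 1 produces LGN channels whose evoked latency grows
    by ``channel_stagger_ms`` per channel (for channel-selection tests).
    """
    if protocol.kind != "flash":
        raise ValueError("generate_evoked_trials requires a flash protocol")
    rng = _as_rng(seed)
    duration = protocol.n_trials * protocol.inter_trial_s
    n = round(duration * RATE_FS_HZ)
    t = np.arange(n) / RATE_FS_HZ
    onsets = np.arange(protocol.n_trials) * protocol.inter_trial_s

    mature = age.name == "P13_14"
    lgn_latency_s = 0.030  # evoked LGN onset after the flash
    vc_latency_s = 0.050
    if mature:
        primary = dict(window=(0.0, 0.05), amp_hz=120.0, freq_hz=None)
        secondary = dict(window=(0.2, 1.0), amp_hz=3.0, freq_hz=None)
    else:
        primary = dict(window=(0.0, 0.2), amp_hz=80.0, freq_hz=EGO_FREQ_HZ)
        secondary = dict(window=(0.2, 1.0), amp_hz=40.0, freq_hz=age.spindle_freq_hz)

    def component_rate(base_latency_s: float, amp_scale: float = 1.0) -> np.ndarray:
        rate = np.full(n, baseline_hz)
        for on in onsets:
            for comp in (primary, secondary):
                w0, w1 = comp["window"]
                a, b = on + base_latency_s + w0, on + base_latency_s + w1
                sl = slice(int(a * RATE_FS_HZ), min(int(b * RATE_FS_HZ), n))
                tt = t[sl] - a
                if comp["freq_hz"] is None:
                    rate[sl] += amp_scale * comp["amp_hz"]
                else:
                    # phase-locked to the stimulus so trial-summed counts
                    # retain the oscillation
                    rate[sl] += amp_scale * comp["amp_hz"] * (
                        1.0 + 0.8 * np.sin(2.0 * np.pi * comp["freq_hz"] * tt)
                    )
        return rate

    span = (0.0, duration)
    trains = []
    for ch in range(n_channels):
        lat = lgn_latency_s + ch * channel_stagger_ms / 1000.0
        trains.append(
            SpikeTrain("LGN", ch, spikes_from_rate(component_rate(lat), rng), span)
        )
    trains.append(
        SpikeTrain("VC", 0, spikes_from_rate(component_rate(vc_latency_s, 0.75), rng), span)
    )

    stimuli = [
        StimulusEvent("flash", float(on), {"pulse_dur_ms": protocol.pulse_dur_ms})
        for on in onsets
    ]
    meta = {
        "kind": "evoked",
        "age": age.name,
        "seed": seed,
        "baseline_hz": baseline_hz,
        "lgn_latency_s": lgn_latency_s,
        "vc_latency_s": vc_latency_s,
        "channel_stagger_ms": channel_stagger_ms,
        "primary": primary,
        "secondary": secondary,
    }
    return RecordingSession(spike_trains=trains, stimuli=stimuli, meta=meta)


# --------------------------------------------------------------------------
# optogenetic trials
# --------------------------------------------------------------------------

#: cortical activation delay after light onset (ms) and volley shape
VC_OPTO_LATENCY_MS = 3.5
VC_VOLLEY_DUR_MS = 10.0
VC_VOLLEY_RATE_HZ = 400.0
LGN_VOLLEY_DUR_MS = 30.0
LGN_VOLLEY_RATE_HZ = 300.0
#: post-pulse suppression window (s, relative to pulse) under inhibition
INHIBITION_WINDOW_S = (0.100, 0.250)
INHIBITION_RESIDUAL = 0.05


def generate_opto_trials(
    age: AgeProfile,
    protocol: StimulusProtocol,
    seed: int = 0,
    lgn_baseline_hz: float = 2.0,
    vc_baseline_hz: float = 1.0,
    latency_jitter_ms: Optional[float] = None,
) -> RecordingSession:
    """Simulate cortical optogenetic stimulation with thalamic responses.

    Per pulse: a VC spike volley at ~3.5 ms latency; an LGN volley
    (~30 ms) at the profile's ``opto_latency_ms``, occurring with
    probability ``opto_reliability``. With inhibition enabled (P13-14)
    the LGN rate is suppressed to a small residual 100-250 ms after each
    pulse, and train pulses arriving during suppression fail to evoke a
    volley. ``meta["pulse_log"]`` records every pulse's ground truth.

    ``latency_jitter_ms`` defaults to the profile's ``opto_jitter_ms``;
    during trains the per-pulse dispersion ``opto_train_dispersion_ms``
    accumulates on top of it (large before stage III waves mature, which
    is what washes out 20 Hz entrainment at P5-7 despite per-pulse
    firing).
    """
    if protocol.kind not in ("opto_single", "opto_train"):
        raise ValueError("generate_opto_trials requires an opto protocol")
    if latency_jitter_ms is None:
        latency_jitter_ms = age.opto_jitter_ms
    rng = _as_rng(seed)
    duration = protocol.n_trials * protocol.inter_trial_s
    n = round(duration * RATE_FS_HZ)
    span = (0.0, duration)

    # trial onsets centred in the inter-trial interval: every trial has a
    # full pre-stimulus baseline
    trial_onsets = (np.arange(protocol.n_trials) + 0.5) * protocol.inter_trial_s

    if protocol.kind == "opto_train":
        pulse_offsets = np.arange(protocol.train_n_pulses) / protocol.train_freq_hz
    else:
        pulse_offsets = np.array([0.0])

    lgn_rate = np.full(n, lgn_baseline_hz)
    vc_rate = np.full(n, vc_baseline_hz)
    pulse_log: list[dict] = []

    def add_volley(rate: np.ndarray, start_s: float, dur_ms: float, amp_hz: float) -> None:
        sl = slice(int(start_s * RATE_FS_HZ), min(int((start_s + dur_ms / 1000.0) * RATE_FS_HZ), n))
        rate[sl] += amp_hz

    for trial, on in enumerate(trial_onsets):
        suppression_until = -np.inf
        for j, off in enumerate(pulse_offsets):
            p_on = float(on + off)
            # cortex always fires (direct channelrhodopsin activation)
            vc_lat = VC_OPTO_LATENCY_MS + rng.normal(0.0, latency_jitter_ms / 2.0)
            add_volley(vc_rate, p_on + vc_lat / 1000.0, VC_VOLLEY_DUR_MS, VC_VOLLEY_RATE_HZ)

            suppressed = age.inhibition_enabled and p_on < suppression_until
            responded = (not suppressed) and (rng.uniform() < age.opto_reliability)
            # timing disperses across a train: later pulses answer with
            # progressively smeared volleys (tonic firing) when the
            # pathway's train dispersion is large, as in the immature
            # circuit
            sigma_j = np.hypot(latency_jitter_ms, age.opto_train_dispersion_ms * j)
            lgn_lat = age.opto_latency_ms + rng.normal(0.0, sigma_j)
            if responded:
                add_volley(lgn_rate, p_on + lgn_lat / 1000.0, LGN_VOLLEY_DUR_MS, LGN_VOLLEY_RATE_HZ)
            if age.inhibition_enabled:
                # feedforward inhibition follows every cortical volley
                a = p_on + INHIBITION_WINDOW_S[0]
                b = p_on + INHIBITION_WINDOW_S[1]
                sl = slice(int(a * RATE_FS_HZ), min(int(b * RATE_FS_HZ), n))
                lgn_rate[sl] = lgn_rate[sl] * INHIBITION_RESIDUAL
                suppression_until = max(suppression_until, b)
            pulse_log.append(
                {
                    "trial": trial,
                    "pulse": j,
                    "onset_s": p_on,
                    "responded": bool(responded),
                    "suppressed": bool(suppressed),
                    "lgn_latency_ms": float(lgn_lat),
                }
            )

    trains = [
        SpikeTrain("LGN", 0, spikes_from_rate(lgn_rate, rng), span),
        SpikeTrain("VC", 0, spikes_from_rate(vc_rate, rng), span),
    ]
    kind = "opto" if protocol.kind == "opto_single" else "opto_train"
    stim_params = {"pulse_dur_ms": protocol.pulse_dur_ms}
    if protocol.kind == "opto_train":
        stim_params.update(
            train_freq_hz=protocol.train_freq_hz, train_n_pulses=protocol.train_n_pulses
        )
    stimuli = [StimulusEvent(kind, float(on), dict(stim_params)) for on in trial_onsets]
    meta = {
        "kind": kind,
        "age": age.name,
        "seed": seed,
        "lgn_baseline_hz": lgn_baseline_hz,
        "vc_baseline_hz": vc_baseline_hz,
        "opto_latency_ms": age.opto_latency_ms,
        "opto_reliability": age.opto_reliability,
        "inhibition_enabled": age.inhibition_enabled,
        "pulse_log": pulse_log,
    }
    return RecordingSession(spike_trains=trains, stimuli=stimuli, meta=meta)


# --------------------------------------------------------------------------
# wideband rendering (for MUA-extraction tests)
# --------------------------------------------------------------------------

def spike_waveform(fs_hz: float, amp_uv: float = -80.0) -> np.ndarray:
    """A biphasic extracellular spike waveform (~1 ms): a sharp negative
    lobe followed by a smaller positive rebound."""
    t = np.arange(round(1.2e-3 * fs_hz)) / fs_hz
    neg = amp_uv * np.exp(-0.5 * ((t - 0.25e-3) / 0.1e-3) ** 2)
    pos = -0.35 * amp_uv * np.exp(-0.5 * ((t - 0.65e-3) / 0.2e-3) ** 2)
    return neg + pos


def render_wideband(
    train: SpikeTrain,
    fs_hz: float = 10000.0,
    amp_uv: float = -80.0,
    noise_sd_uv: float = 4.0,
    seed=0,
) -> LfpTrace:
    """Render a spike train as a wideband voltage trace: each spike stamps
    a biphasic waveform (negative peak at the spike time) onto Gaussian
    background noise."""
    rng = _as_rng(seed)
    n = round(train.duration_s * fs_hz)
    x = rng.standard_normal(n) * noise_sd_uv
    w = spike_waveform(fs_hz, amp_uv)
    peak = int(np.argmin(w))
    for t_sp in train.times_s - train.span_s[0]:
        i0 = int(round(t_sp * fs_hz)) - peak
        a, b = max(i0, 0), min(i0 + w.size, n)
        if b > a:
            x[a:b] += w[a - i0 : b - i0]
    return LfpTrace(samples=x, fs_hz=fs_hz, channel=train.channel, region=train.region)


# --------------------------------------------------------------------------
# spectrum-level population fixtures (for the statistics module)
# --------------------------------------------------------------------------

def sample_spectrum_population(
    n_animals: int,
    freq_hz: np.ndarray,
    rng,
    peak_hz: float = 23.0,
    peak_width_hz: float = 4.0,
    noise_sd: float = 0.15,
    band_hz: Optional[tuple[float, float]] = None,
    band_scale: float = 1.0,
) -> np.ndarray:
    """Per-animal normalized power spectra with multiplicative noise.

    The population mean is a 1/f-ish floor plus a spindle-band Gaussian
    peak; each animal's spectrum is the mean times independent
    ``1 + N(0, noise_sd)`` per frequency, normalized to unit mean over
    2-55 Hz. Power inside ``band_hz`` is then scaled by ``band_scale``
    *after* normalization, so a silencing-like band-limited effect stays
    confined to the band instead of leaking everywhere through the
    normalization denominator.
    """
    rng = _as_rng(rng)
    freq_hz = np.asarray(freq_hz, dtype=float)
    base = 0.5 + 2.0 / (1.0 + freq_hz / 10.0) + 2.5 * np.exp(
        -0.5 * ((freq_hz - peak_hz) / peak_width_hz) ** 2
    )
    spectra = base[None, :] * np.clip(
        1.0 + noise_sd * rng.standard_normal((n_animals, freq_hz.size)), 0.05, None
    )
    norm = (freq_hz >= 2.0) & (freq_hz <= 55.0)
    spectra /= spectra[:, norm].mean(axis=1, keepdims=True)
    if band_hz is not None:
        in_band = (freq_hz >= band_hz[0]) & (freq_hz <= band_hz[1])
        spectra[:, in_band] *= band_scale
    return spectra
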