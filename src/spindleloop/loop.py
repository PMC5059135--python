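"""Delayed corticothalamic feedback-loop rate model.

A minimal mechanistic embodiment of spindle-burst rhythmogenesis in the
LGN-VC loop: retinal drive ``R(t)`` enters the thalamus, cortex reads the
thalamic rate with an axonal/synaptic delay, and feeds back
multiplicatively (net excitatory before eye-opening) plus an optional
delayed subtractive inhibition (the mature circuit):

    C(t) = max(0, a * L(t - d_LGN->VC))
    L(t) = max(floor, R(t) * (1 + g_fb * C(t - d_VC->LGN))
                      - g_inh * C(t - d_VC->LGN - d_inh))

With constant drive the loop is a pure amplifier with DC gain
``1 / (1 - G)`` where ``G = mean(R) * g_fb * a`` is the round-trip gain.
Rhythm arises as *comb resonance*: broadband fluctuations in the retinal
drive are selectively amplified at multiples of the inverse loop delay
``1 / (d_LGN->VC + d_VC->LGN)`` (25 Hz for 20 + 20 ms), the harmonics
being suppressed because retinal drive fluctuations are slow. Delayed
inhibition spoils the resonance and quenches the oscillation.

Defaults are calibrated so the closed-loop thalamic rate is ~5x the open
loop (i.e. feedback supplies ~80% of thalamic firing): ``G = 0.8``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Union

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .session import RecordingSession, SpikeTrain
from .simulate import spikes_from_rate


class LoopInstabilityError(RuntimeError):
    """Raised when the simulated rate exceeds the configured ceiling."""


@dataclass
class LoopModelParams:
    """Parameters of the delayed-rate loop model.

    Attributes
    ----------
    dt_ms : float
        Integration step; must not exceed a quarter of the smallest delay.
    delay_lgn_to_vc_ms, delay_vc_to_lgn_ms : float
        One-way conduction + synaptic delays of the loop.
    feedback_gain : float
        ``g_fb`` — multiplicative corticothalamic facilitation per unit
        cortical rate. The default, with ``cortical_gain`` and
        ``drive_mean_hz``, gives round-trip gain 0.8.
    inhibition_gain, inhibition_delay_ms : float
        ``g_inh`` (Hz of suppression per unit cortical rate) acting at an
        extra delay — the feedforward-inhibition branch; 0 disables it.
    cortical_gain : float
        ``a`` — cortical rate per unit delayed thalamic rate (~0.25:
        cortex fires at a fraction of the thalamic rate).
    drive_mean_hz, drive_noise_sd_hz, drive_smooth_ms : float
        Statistics of the default stochastic retinal drive: Gaussian
        fluctuations low-pass smoothed to ~4 ms, mimicking slow retinal
        rate fluctuations (broadband below ~40 Hz).
    retinal_drive : ndarray or callable or None
        Explicit drive trace in Hz (overrides the stochastic default).
    rate_floor_hz, rate_ceiling_hz : float
        Rates are clipped below at the floor; exceeding the ceiling
        aborts with :class:`LoopInstabilityError`.
    """

    dt_ms: float = 1.0
    delay_lgn_to_vc_ms: float = 20.0
    delay_vc_to_lgn_ms: float = 20.0
    feedback_gain: float = 0.16
    inhibition_gain: float = 0.0
    inhibition_delay_ms: float = 40.0
    cortical_gain: float = 0.25
    drive_mean_hz: float = 20.0
    drive_noise_sd_hz: float = 5.0
    drive_smooth_ms: float = 4.0
    retinal_drive: Optional[Union[np.ndarray, Callable[[np.ndarray], np.ndarray]]] = None
    rate_floor_hz: float = 0.0
    rate_ceiling_hz: float = 2000.0
    seed: int = 0

    def __post_init__(self) -> None:
        min_delay = min(self.delay_lgn_to_vc_ms, self.delay_vc_to_lgn_ms)
        if self.dt_ms > min_delay / 4.0:
            raise ValueError(
                f"dt_ms={self.dt_ms} too coarse: must be <= min delay / 4 = {min_delay / 4.0} ms"
            )
        for name in ("feedback_gain", "inhibition_gain", "cortical_gain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.inhibition_delay_ms < self.dt_ms or min_delay < self.dt_ms:
            raise ValueError("delays must be >= dt_ms")

    @property
    def loop_period_s(self) -> float:
        """Round-trip delay: the resonance period of the intact loop."""
        return (self.delay_lgn_to_vc_ms + self.delay_vc_to_lgn_ms) / 1000.0

    @property
    def round_trip_gain(self) -> float:
        return self.drive_mean_hz * self.feedback_gain * self.cortical_gain


def _default_drive(params: LoopModelParams, n: int, rng: np.random.Generator) -> np.ndarray:
    noise = rng.standard_normal(n)
    sigma = params.drive_smooth_ms / params.dt_ms
    if sigma > 0:
        noise = gaussian_filter1d(noise, sigma=sigma)
        noise /= max(noise.std(), 1e-12)  # unit variance after smoothing
    return np.clip(params.drive_mean_hz + params.drive_noise_sd_hz * noise, 0.0, None)


def simulate_feedback_loop(params: LoopModelParams, duration_s: float) -> RecordingSession:
    """Integrate the delayed-rate loop and emit Poisson spikes from both
    the thalamic (LGN) and cortical (VC) rate traces.

    The deterministic rate traces are stored in ``meta`` (``lgn_rate_hz``,
    ``vc_rate_hz``, ``drive_hz``, ``dt_s``) so spectral properties can be
    assessed without Poisson sampling noise.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    dt = params.dt_ms / 1000.0
    fs = 1.0 / dt
    n = round(duration_s * fs)
    rng = np.random.default_rng(params.seed)

    if params.retinal_drive is None:
        drive = _default_drive(params, n, rng)
    elif callable(params.retinal_drive):
        drive = np.asarray(params.retinal_drive(np.arange(n) * dt), dtype=float)
    else:
        drive = np.asarray(params.retinal_drive, dtype=float)
        if drive.size < n:
            raise ValueError(f"retinal_drive has {drive.size} samples; need {n}")
        drive = drive[:n]
    if np.any(drive < 0):
        raise ValueError("retinal drive must be nonnegative")

    d_cl = round(params.delay_vc_to_lgn_ms / params.dt_ms)  # cortex -> thalamus
    d_lc = round(params.delay_lgn_to_vc_ms / params.dt_ms)  # thalamus -> cortex
    d_in = round(params.inhibition_delay_ms / params.dt_ms)

    L = np.zeros(n)
    C = np.zeros(n)
    g_fb, g_inh, a = params.feedback_gain, params.inhibition_gain, params.cortical_gain
    floor, ceiling = params.rate_floor_hz, params.rate_ceiling_hz
    for t in range(n):
        c_fb = C[t - d_cl] if t >= d_cl else 0.0
        c_in = C[t - d_cl - d_in] if t >= d_cl + d_in else 0.0
        lt = drive[t] * (1.0 + g_fb * c_fb) - g_inh * c_in
        L[t] = lt if lt > floor else floor
        if L[t] > ceiling:
            raise LoopInstabilityError(
                f"thalamic rate {L[t]:.1f} Hz exceeded ceiling {ceiling} Hz at "
                f"t={t * dt:.3f} s (round-trip gain {params.round_trip_gain:.2f}); "
                "reduce feedback_gain, cortical_gain or drive"
            )
        lc = L[t - d_lc] if t >= d_lc else 0.0
        ct = a * lc
        C[t] = ct if ct > 0.0 else 0.0

    span = (0.0, n * dt)
    trains = [
        SpikeTrain("LGN", 0, spikes_from_rate(L, rng, fs_hz=fs), span),
        SpikeTrain("VC", 0, spikes_from_rate(C, rng, fs_hz=fs), span),
    ]
    meta = {
        "kind": "loop",
        "seed": params.seed,
        "dt_s": dt,
        "lgn_rate_hz": L,
        "vc_rate_hz": C,
        "drive_hz": drive,
        "round_trip_gain": params.round_trip_gain,
        "loop_period_s": params.loop_period_s,
    }
    return RecordingSession(spike_trains=trains, meta=meta)


def rate_trace_spectrum(
    rate_hz: np.ndarray, dt_s: float, window_s: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """Welch periodogram of a (deterministic) rate trace, mean subtracted.

    The independent oracle for loop rhythmogenesis: returns
    ``(freq_hz, power)`` at ``1 / window_s`` resolution.
    """
    from scipy.signal import welch

    fs = 1.0 / dt_s
    nper = round(window_s * fs)
    f, p = welch(rate_hz - rate_hz.mean(), fs=fs, nperseg=nper, detrend=False)
    return f, p
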