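"""Age-group parameter profiles for the synthetic recordings.

Three developmental windows of the rat visual system are modelled:

``P5_7``
    Stage II (cholinergic) retinal waves. Slow spindle-burst modulation
    (~16 Hz in LGN spike rate), short 1-5 s firing periods separated by
    10-60 s of network silence, slow and unreliable corticothalamic
    activation (latency ~34 ms, reliability ~0.4), no feedforward
    inhibition.

``P9_11``
    Peak of stage III (glutamatergic) waves. Fast spindle-bursts
    (~23 Hz spike-rate modulation), 3-10 s active periods, fast and
    moderately reliable corticothalamic loop (latency ~21.5 ms), still
    no effective inhibition — the age at which 20 Hz cortical drive
    entrains the thalamus.

``P13_14``
    After the wave period / around eyelid opening. Corticothalamic
    latency stabilised (~20 ms), reliability high (~0.92), and
    feedforward inhibition is functional: excitation is followed by a
    100-250 ms suppression of thalamic firing that defeats entrainment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional


@dataclass(frozen=True)
class AgeProfile:
    """Generator parameters tied to one developmental age group.

    Attributes
    ----------
    name : str
        ``"P5_7"``, ``"P9_11"`` or ``"P13_14"``.
    spindle_freq_hz : float
        Centre frequency of the oscillatory spike-rate modulation during
        active periods (spindle-burst band).
    spindle_freq_no_feedback_hz : float or None
        Modulation frequency when visual cortex is silenced (the
        retina/thalamus-only rhythm); ``None`` means unchanged.
    active_dur_s, silent_dur_s : (float, float)
        Uniform ranges for active-period and silent-period durations.
    opto_latency_ms : float
        Latency from cortical optogenetic activation to the thalamic
        spike volley.
    opto_reliability : float
        Probability in [0, 1] that a cortical volley elicits a thalamic
        response.
    opto_jitter_ms : float
        Trial-to-trial SD of the thalamic volley latency for a single
        pulse.
    opto_train_dispersion_ms : float
        Additional latency dispersion accumulated per pulse position
        during repetitive stimulation; the immature pathway answers
        later pulses with progressively smeared, tonic firing, which is
        what prevents 20 Hz entrainment before stage III waves mature.
    inhibition_enabled : bool
        Whether cortically recruited feedforward inhibition suppresses
        thalamic firing 100-250 ms after a pulse.
    """

    name: str
    spindle_freq_hz: float
    active_dur_s: tuple[float, float]
    silent_dur_s: tuple[float, float]
    opto_latency_ms: float
    opto_reliability: float
    inhibition_enabled: bool
    spindle_freq_no_feedback_hz: Optional[float] = None
    opto_jitter_ms: float = 1.0
    opto_train_dispersion_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.spindle_freq_hz <= 0:
            raise ValueError("spindle_freq_hz must be positive")
        for lo, hi in (self.active_dur_s, self.silent_dur_s):
            if lo > hi or lo < 0:
                raise ValueError("duration ranges must satisfy 0 <= min <= max")
        if not 0.0 <= self.opto_reliability <= 1.0:
            raise ValueError("opto_reliability must lie in [0, 1]")

    def with_(self, **kw) -> "AgeProfile":
        """A copy with some fields replaced."""
        return replace(self, **kw)


P5_7 = AgeProfile(
    name="P5_7",
    spindle_freq_hz=16.0,
    spindle_freq_no_feedback_hz=16.0,  # cortical silencing does not shift the rhythm at this age
    active_dur_s=(1.0, 5.0),
    silent_dur_s=(10.0, 60.0),
    opto_latency_ms=34.2,
    opto_reliability=0.397,
    inhibition_enabled=False,
    opto_jitter_ms=2.0,
    opto_train_dispersion_ms=15.0,
)

P9_11 = AgeProfile(
    name="P9_11",
    spindle_freq_hz=23.1,
    spindle_freq_no_feedback_hz=16.2,  # loses cortical acceleration when VC is silenced
    active_dur_s=(3.0, 10.0),
    silent_dur_s=(10.0, 60.0),
    opto_latency_ms=21.5,
    opto_reliability=0.75,
    inhibition_enabled=False,
    opto_jitter_ms=1.5,
    opto_train_dispersion_ms=1.5,
)

P13_14 = AgeProfile(
    name="P13_14",
    spindle_freq_hz=23.1,
    spindle_freq_no_feedback_hz=None,
    active_dur_s=(3.0, 10.0),
    silent_dur_s=(5.0, 30.0),
    opto_latency_ms=20.0,
    opto_reliability=0.924,
    inhibition_enabled=True,
    opto_jitter_ms=1.0,
    opto_train_dispersion_ms=1.0,
)

AGE_PROFILES: dict[str, AgeProfile] = {p.name: p for p in (P5_7, P9_11, P13_14)}


def get_profile(name: str) -> AgeProfile:
    try:
        return AGE_PROFILES[name]
    except KeyError:
        raise KeyError(f"unknown age profile {name!r}; known: {sorted(AGE_PROFILES)}") from None
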