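"""The delayed corticothalamic feedback loop: amplification and rhythm.

Integrates the two-delay rate model (retina -> LGN -> VC -> LGN) in
three configurations: the intact excitatory loop, the open loop
(feedback gain 0, as after cortical silencing), and the mature loop with
delayed feedforward inhibition. Prints the thalamic rate and the peak of
the rate-trace spectrum.
"""

import numpy as np

import spindleloop as sl
from spindleloop.loop import rate_trace_spectrum

DURATION_S = 120.0


def describe(name, session):
    rate = session.meta["lgn_rate_hz"]
    f, p = rate_trace_spectrum(rate, session.meta["dt_s"])
    band = (f >= 5) & (f <= 55)
    peak = f[band][np.argmax(p[band])]
    i25 = np.argmin(np.abs(f - 25.0))
    print(f"{name:<22} mean LGN rate {rate.mean():6.1f} Hz   "
          f"peak {peak:5.1f} Hz   power@25Hz {p[i25]:.3g}")
    return p[i25]


closed = sl.simulate_feedback_loop(sl.LoopModelParams(seed=1), DURATION_S)
opened = sl.simulate_feedback_loop(sl.LoopModelParams(seed=1, feedback_gain=0.0), DURATION_S)
inhib = sl.simulate_feedback_loop(sl.LoopModelParams(seed=1, inhibition_gain=2.0), DURATION_S)

p_closed = describe("intact loop:", closed)
describe("open loop (VC off):", opened)
p_inhib = describe("with inhibition:", inhib)
print(f"\ninhibition leaves {100 * p_inhib / p_closed:.0f}% of the 25 Hz resonance power")

# With 20 + 20 ms delays and round-trip gain 0.8 the loop amplifies the
# retinal drive ~5x (feedback supplies ~80% of thalamic firing) and
# resonates at 1/(40 ms) = 25 Hz — the spindle-burst rhythm. Opening the
# loop drops the rate to the drive level and abolishes the peak; delayed
# inhibition (the post-eye-opening circuit) quenches it.
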