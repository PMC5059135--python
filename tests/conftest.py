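import numpy as np
import pytest

import spindleloop as sl


@pytest.fixture(scope="session")
def short_wave_session():
    """A 120 s spontaneous P9-11 session shared across read-only tests."""
    return sl.generate_wave_recording(
        sl.P9_11, sl.WaveGeneratorParams(duration_s=120.0, seed=42)
    )


@pytest.fixture(scope="session")
def opto_session_p9():
    proto = sl.StimulusProtocol(
        kind="opto_single", pulse_dur_ms=10.0, inter_trial_s=10.0, n_trials=100
    )
    return sl.generate_opto_trials(sl.P9_11, proto, seed=42)


def log_grid_index(freq_hz: float, grid: np.ndarray) -> int:
    """Index of the nearest log-grid bin (log-distance)."""
    return int(np.argmin(np.abs(np.log(grid) - np.log(freq_hz))))
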