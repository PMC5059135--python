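"""Session serialization and plain-text spike-file input.

A session directory holds:

* ``spikes.csv``   — region, channel, time_s (1e-6 s precision)
* ``stimuli.csv``  — kind, onset_s, params (JSON)
* ``session.json`` — span, metadata (age mode, manipulation, seed, ...)
* ``lfp.bin`` + ``lfp.json`` — float32 little-endian samples with a
  sidecar naming sampling rate, channels and regions (written only when
  LFP is present)

Plain two-column delimited spike files (channel, time_s) are also
accepted as input.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .session import LfpTrace, RecordingSession, SpikeTrain, StimulusEvent

TIME_FORMAT = "%.6f"  # 1 microsecond precision round-trips losslessly


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_session(session: RecordingSession, path: str | Path) -> Path:
    """Write a session directory; returns the path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    rows = []
    for tr in session.spike_trains:
        for t in tr.times_s:
            rows.append((tr.region, tr.channel, t))
    spikes = pd.DataFrame(rows, columns=["region", "channel", "time_s"])
    spikes.to_csv(path / "spikes.csv", index=False, float_format=TIME_FORMAT)

    stim = pd.DataFrame(
        [
            (ev.kind, ev.onset_s, json.dumps(_jsonable(ev.params), sort_keys=True))
            for ev in session.stimuli
        ],
        columns=["kind", "onset_s", "params"],
    )
    stim.to_csv(path / "stimuli.csv", index=False, float_format=TIME_FORMAT)

    meta = {k: v for k, v in session.meta.items() if not isinstance(v, np.ndarray)}
    doc = {
        "span_s": list(session.span_s),
        "channels": [
            {"region": tr.region, "channel": tr.channel, "n_spikes": len(tr)}
            for tr in session.spike_trains
        ],
        "meta": _jsonable(meta),
    }
    (path / "session.json").write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")

    if session.lfp:
        samples = np.stack([tr.samples for tr in session.lfp]).astype("<f4")
        samples.tofile(path / "lfp.bin")
        sidecar = {
            "dtype": "float32-le",
            "shape": list(samples.shape),
            "fs_hz": session.lfp[0].fs_hz,
            "channels": [{"region": t.region, "channel": t.channel} for t in session.lfp],
        }
        (path / "lfp.json").write_text(json.dumps(sidecar, indent=1, sort_keys=True) + "\n")
    return path


def read_session(path: str | Path) -> RecordingSession:
    """Read a session directory written by :func:`write_session`."""
    path = Path(path)
    doc = json.loads((path / "session.json").read_text())
    span = tuple(doc["span_s"])

    spikes = pd.read_csv(path / "spikes.csv")
    trains = []
    for ch in doc["channels"]:
        sel = spikes[(spikes.region == ch["region"]) & (spikes.channel == ch["channel"])]
        trains.append(
            SpikeTrain(
                region=ch["region"],
                channel=int(ch["channel"]),
                times_s=np.sort(sel.time_s.to_numpy(dtype=float)),
                span_s=span,
            )
        )

    stim_path = path / "stimuli.csv"
    stimuli = []
    if stim_path.exists():
        stim = pd.read_csv(stim_path)
        for _, row in stim.iterrows():
            stimuli.append(
                StimulusEvent(str(row["kind"]), float(row["onset_s"]), json.loads(row["params"]))
            )

    lfp = None
    if (path / "lfp.json").exists():
        sidecar = json.loads((path / "lfp.json").read_text())
        raw = np.fromfile(path / "lfp.bin", dtype="<f4").reshape(sidecar["shape"])
        lfp = [
            LfpTrace(
                samples=raw[i].astype(float),
                fs_hz=sidecar["fs_hz"],
                channel=int(c["channel"]),
                region=c["region"],
            )
            for i, c in enumerate(sidecar["channels"])
        ]
    return RecordingSession(spike_trains=trains, lfp=lfp, stimuli=stimuli, meta=doc.get("meta", {}))


def load_spike_file(
    path: str | Path,
    span_s: tuple[float, float] | None = None,
    region: str = "other",
    delimiter: str | None = None,
) -> list[SpikeTrain]:
    """Read a plain two-column delimited spike file (channel, time_s);
    returns one train per channel. The span defaults to (0, max time)."""
    arr = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    if arr.shape[1] != 2:
        raise ValueError(f"expected two columns (channel, time_s); got {arr.shape[1]}")
    channels = np.unique(arr[:, 0]).astype(int)
    if span_s is None:
        span_s = (0.0, float(arr[:, 1].max()) if arr.size else 1.0)
    return [
        SpikeTrain(
            region=region,
            channel=int(ch),
            times_s=np.sort(arr[arr[:, 0] == ch, 1]),
            span_s=span_s,
        )
        for ch in channels
    ]


def write_events_csv(event_set, path: str | Path) -> Path:
    """events.csv: start_s, stop_s, n_spikes, duration_s."""
    path = Path(path)
    df = pd.DataFrame(
        [
            (a, b, n, b - a)
            for (a, b), n in zip(event_set.events, event_set.n_spikes)
        ],
        columns=["start_s", "stop_s", "n_spikes", "duration_s"],
    )
    df.to_csv(path, index=False, float_format=TIME_FORMAT)
    return path


def write_spectrum_csv(spectrum, path: str | Path) -> Path:
    """spectra.csv: freq_hz, power plus provenance flags."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "freq_hz": spectrum.freq_hz,
            "power": spectrum.power,
            "compensated": spectrum.compensated,
            "log_resampled": spectrum.log_resampled,
            "normalized": spectrum.normalized,
        }
    )
    df.to_csv(path, index=False, float_format="%.9g")
    return path
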