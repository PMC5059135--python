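"""End-to-end experiments: simulate -> preprocess -> analyze -> report.

Two orchestrated experiment shapes:

* **silencing** — n paired sessions (control / manipulated, same
  per-animal seed), compared by percent change of rate and continuity
  (Wilcoxon signed-rank), event-duration distributions (KS + DKW
  bands), and normalized MUA spectra (paired permutation test with
  max-statistic correction);
* **stimulation** — per age mode: optogenetic single-pulse PSTHs with
  LGN-VC onset delay, reliability, excitation/inhibition window
  changes, 20 Hz train entrainment, and flash-evoked primary/secondary
  responses.

Per-animal seeds are derived from the master seed and the animal /
condition indices, so adding animals never perturbs existing ones.
Reports (CSV + JSON + one markdown summary) contain no timestamps or
environment state: identical seeds give byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as sio
from .events import compute_continuity, detect_events, event_duration_distribution, percent_change
from .preprocess import bin_spike_train
from .profiles import AGE_PROFILES, AgeProfile, get_profile
from .responses import (
    ResponseWindows,
    compute_psth,
    entrainment_index,
    lgn_vc_onset_delay,
    response_reliability,
    split_primary_secondary,
    window_rate_change,
)
from .simulate import (
    ManipulationSpec,
    StimulusProtocol,
    WaveGeneratorParams,
    generate_evoked_trials,
    generate_opto_trials,
    generate_wave_recording,
)
from .spectral import SpectralParams, mua_spectrum, peak_frequency
from .stats import ks_two_sample_with_ci, permutation_spectrum_test, wilcoxon_signed_rank


def derive_seed(master_seed: int, *key: int) -> int:
    """A per-animal / per-condition seed from the master seed, stable
    under adding animals (< 2**31)."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class ExperimentConfig:
    """Configuration of a full experiment.

    Defaults follow the study conditions: n = 6 animals, a 20 min
    control and a 20 min post-manipulation period per animal at 1 ms
    resolution, events as >= 2 spikes with ISI < 500 ms, spectra
    normalized over 2-55 Hz.
    """

    seed: int
    age: str = "P9_11"
    n_animals: int = 6
    condition_duration_s: float = 1200.0
    manipulation: ManipulationSpec = field(
        default_factory=lambda: ManipulationSpec(target="retina", residual_fraction=0.1)
    )
    generator: WaveGeneratorParams = field(default_factory=WaveGeneratorParams)
    spectral: SpectralParams = field(default_factory=SpectralParams)
    iei_threshold_s: float = 0.5
    min_spikes: int = 2
    alpha: float = 0.05
    n_perm: int = 10000
    region: str = "LGN"
    out_dir: Optional[str] = None
    opto_trials: int = 100
    opto_inter_trial_s: float = 10.0
    train_trials: int = 50
    train_inter_trial_s: float = 2.0
    flash_trials: int = 30

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        if "seed" not in raw:
            raise ValueError("config field 'seed' is mandatory")
        kwargs = dict(raw)
        try:
            if "manipulation" in kwargs:
                kwargs["manipulation"] = ManipulationSpec(**kwargs["manipulation"])
            if "generator" in kwargs:
                kwargs["generator"] = WaveGeneratorParams(**kwargs["generator"])
            if "spectral" in kwargs:
                sp = dict(kwargs["spectral"])
                for key in ("tapers", "norm_band_hz", "log_grid"):
                    if key in sp:
                        sp[key] = tuple(sp[key])
                kwargs["spectral"] = SpectralParams(**sp)
        except TypeError as exc:
            raise ValueError(f"config validation failed: {exc}") from exc
        unknown = set(kwargs) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**kwargs)

    def profile(self) -> AgeProfile:
        return get_profile(self.age)


def _fmt(x: float) -> float:
    """Round for stable, byte-identical JSON output."""
    return float(np.format_float_positional(x, precision=9, unique=False, fractional=False))


def _write_json(doc: dict, path: Path) -> None:
    path.write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def run_silencing_experiment(config: ExperimentConfig) -> dict:
    """Paired control / silencing comparison over n simulated animals.

    Returns (and optionally writes) a report: per-animal rates,
    continuity, percent changes with Wilcoxon p-values, pooled
    event-duration distributions with KS test, and per-animal normalized
    spectra with the permutation-test significant ranges.
    """
    profile = config.profile()
    sham = ManipulationSpec(target="none")
    rows = []
    durations = {"control": [], "silenced": []}
    spectra = {"control": [], "silenced": []}
    freq = None
    for i in range(config.n_animals):
        for cond_idx, (cond, manip) in enumerate(
            (("control", sham), ("silenced", config.manipulation))
        ):
            seed = derive_seed(config.seed, i, cond_idx)
            params = replace(
                config.generator, duration_s=config.condition_duration_s, seed=seed
            )
            session = generate_wave_recording(profile, params, manip)
            train = session.train(config.region)
            events = detect_events(train, config.iei_threshold_s, config.min_spikes)
            cont = compute_continuity(events)
            durations[cond].extend(events.durations_s.tolist())
            spec = mua_spectrum(bin_spike_train(train), config.spectral)
            spectra[cond].append(spec.power)
            freq = spec.freq_hz
            pk = peak_frequency(spec)
            rows.append(
                {
                    "animal": i,
                    "condition": cond,
                    "seed": seed,
                    "rate_hz": _fmt(train.rate_hz),
                    "continuity": _fmt(cont.continuity),
                    "n_events": len(events),
                    "peak_freq_hz": _fmt(pk.freq_hz),
                    "peak_low_confidence": bool(pk.low_confidence),
                }
            )

    per_animal = pd.DataFrame(rows)
    ctrl = per_animal[per_animal.condition == "control"].set_index("animal")
    post = per_animal[per_animal.condition == "silenced"].set_index("animal")
    rate_change = [
        percent_change(ctrl.rate_hz[i], post.rate_hz[i]) for i in range(config.n_animals)
    ]
    cont_change = [
        percent_change(ctrl.continuity[i], post.continuity[i]) for i in range(config.n_animals)
    ]
    w_rate = wilcoxon_signed_rank(ctrl.rate_hz.to_numpy(), post.rate_hz.to_numpy())
    w_cont = wilcoxon_signed_rank(ctrl.continuity.to_numpy(), post.continuity.to_numpy())
    w_peak = wilcoxon_signed_rank(ctrl.peak_freq_hz.to_numpy(), post.peak_freq_hz.to_numpy())

    ks = None
    if durations["control"] and durations["silenced"]:
        ks = ks_two_sample_with_ci(
            durations["control"], durations["silenced"], alpha=config.alpha
        )
    perm = permutation_spectrum_test(
        np.asarray(spectra["control"]),
        np.asarray(spectra["silenced"]),
        freq,
        alpha=config.alpha,
        n_perm=config.n_perm,
        seed=derive_seed(config.seed, 9999),
    )

    report = {
        "experiment": "silencing",
        "age": config.age,
        "seed": config.seed,
        "n_animals": config.n_animals,
        "manipulation": asdict(config.manipulation),
        "rate_change_pct": {
            "per_animal": [_fmt(v) for v in rate_change],
            "mean": _fmt(np.mean(rate_change)),
            "wilcoxon_p": _fmt(w_rate.p_value),
        },
        "continuity_change_pct": {
            "per_animal": [_fmt(v) for v in cont_change],
            "mean": _fmt(np.mean(cont_change)),
            "wilcoxon_p": _fmt(w_cont.p_value),
        },
        "peak_freq_hz": {
            "control_mean": _fmt(ctrl.peak_freq_hz.mean()),
            "silenced_mean": _fmt(post.peak_freq_hz.mean()),
            "wilcoxon_p": _fmt(w_peak.p_value),
        },
        "event_durations": {
            "n_control": len(durations["control"]),
            "n_silenced": len(durations["silenced"]),
            "ks_D": _fmt(ks.statistic) if ks else None,
            "ks_p": _fmt(ks.p_value) if ks else None,
            "over_5s_control": int(np.sum(np.asarray(durations["control"]) > 5.0)),
            "over_5s_silenced": int(np.sum(np.asarray(durations["silenced"]) > 5.0)),
        },
        "spectra": {
            "n_permutations": perm.n_permutations,
            "exhaustive": perm.exhaustive,
            "corrected_threshold": _fmt(perm.corrected_threshold),
            "significant_ranges_hz": [
                [_fmt(a), _fmt(b)] for a, b in perm.significant_ranges_hz
            ],
        },
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        per_animal.to_csv(out / "per_animal.csv", index=False, float_format="%.9g")
        spec_df = pd.DataFrame(
            {
                "freq_hz": freq,
                **{
                    f"{cond}_{i}": spectra[cond][i]
                    for cond in ("control", "silenced")
                    for i in range(config.n_animals)
                },
            }
        )
        spec_df.to_csv(out / "spectra.csv", index=False, float_format="%.9g")
        dur_df = pd.DataFrame(
            [("control", d) for d in durations["control"]]
            + [("silenced", d) for d in durations["silenced"]],
            columns=["condition", "duration_s"],
        )
        dur_df.to_csv(out / "event_durations.csv", index=False, float_format="%.6f")
        _write_json(report, out / "summary.json")
        (out / "report.md").write_text(_silencing_markdown(report))
    return report


def _silencing_markdown(r: dict) -> str:
    ranges = ", ".join(f"{a:.1f}-{b:.1f} Hz" for a, b in r["spectra"]["significant_ranges_hz"]) or "none"
    return (
        f"# Silencing experiment ({r['age']}, seed {r['seed']})\n\n"
        f"Manipulation: {r['manipulation']['target']} -> residual "
        f"{r['manipulation']['residual_fraction']}\n\n"
        f"| quantity | mean change | Wilcoxon p |\n|---|---|---|\n"
        f"| spike rate | {r['rate_change_pct']['mean']:+.1f}% | {r['rate_change_pct']['wilcoxon_p']:.4f} |\n"
        f"| continuity | {r['continuity_change_pct']['mean']:+.1f}% | {r['continuity_change_pct']['wilcoxon_p']:.4f} |\n\n"
        f"Peak frequency: {r['peak_freq_hz']['control_mean']:.1f} -> "
        f"{r['peak_freq_hz']['silenced_mean']:.1f} Hz (p={r['peak_freq_hz']['wilcoxon_p']:.4f})\n\n"
        f"Event durations: n={r['event_durations']['n_control']} vs "
        f"{r['event_durations']['n_silenced']}, KS p={r['event_durations']['ks_p']}\n\n"
        f"Spectral permutation test ({r['spectra']['n_permutations']} permutations): "
        f"significant at {ranges}\n"
    )


def run_stimulation_experiment(config: ExperimentConfig, ages: Optional[list[str]] = None) -> dict:
    """Optogenetic + visual stimulation analysis per age mode.

    For each age: single-pulse PSTH with LGN-VC onset delay, response
    reliability, 1-100 ms and 100-250 ms window rate changes, 20 Hz x 5
    train entrainment, and flash primary/secondary rates and spectral
    peaks.
    """
    ages = ages or list(AGE_PROFILES)
    windows = ResponseWindows()
    report: dict = {"experiment": "stimulation", "seed": config.seed, "ages": {}}
    for k, age_name in enumerate(ages):
        profile = get_profile(age_name)
        seed = derive_seed(config.seed, 100 + k)

        single = StimulusProtocol(
            kind="opto_single",
            pulse_dur_ms=10.0,
            inter_trial_s=config.opto_inter_trial_s,
            n_trials=config.opto_trials,
        )
        s_single = generate_opto_trials(profile, single, seed=seed)
        delay = lgn_vc_onset_delay(s_single, align="opto")
        psth = compute_psth(s_single, "opto", window_s=(-0.1, 0.3))
        excit = window_rate_change(psth, windows.excitation_s)
        inhib = window_rate_change(psth, windows.inhibition_s)
        reliability = response_reliability(s_single, windows, align="opto")

        train = StimulusProtocol(
            kind="opto_train",
            pulse_dur_ms=10.0,
            inter_trial_s=config.train_inter_trial_s,
            n_trials=config.train_trials,
            train_freq_hz=20.0,
            train_n_pulses=5,
        )
        s_train = generate_opto_trials(profile, train, seed=derive_seed(config.seed, 200 + k))
        ent = entrainment_index(s_train, windows)

        flash = StimulusProtocol(
            kind="flash", pulse_dur_ms=100.0, inter_trial_s=30.0, n_trials=config.flash_trials
        )
        s_flash = generate_evoked_trials(
            profile, flash, seed=derive_seed(config.seed, 300 + k)
        )
        split = split_primary_secondary(s_flash, windows)
        p_spec, s_spec = split.spectra()
        p_peak, s_peak = peak_frequency(p_spec, (8.0, 55.0)), peak_frequency(s_spec, (8.0, 55.0))

        report["ages"][age_name] = {
            "opto": {
                "lgn_onset_ms": _fmt(delay["LGN"].latency_ms),
                "vc_onset_ms": _fmt(delay["VC"].latency_ms),
                "lgn_vc_delay_ms": _fmt(delay["delay_ms"]),
                "reliability_pct": _fmt(reliability),
                "excitation_change_pct": _fmt(excit),
                "inhibition_change_pct": _fmt(inhib),
                "n_trials": psth.n_trials,
            },
            "train_20hz": {
                "pulse_probabilities": [_fmt(p) for p in ent.pulse_probabilities],
                "psth_peak_hz": _fmt(ent.psth_peak_hz),
                "entrained": bool(ent.entrained),
            },
            "flash": {
                "primary_rate_hz": _fmt(split.primary.rate_hz.mean()),
                "secondary_rate_hz": _fmt(split.secondary.rate_hz.mean()),
                "baseline_hz": _fmt(psth.baseline_mean_hz),
                "primary_peak_hz": _fmt(p_peak.freq_hz),
                "secondary_peak_hz": _fmt(s_peak.freq_hz),
            },
        }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_json(report, out / "responses.json")
        (out / "report.md").write_text(_stimulation_markdown(report))
    return report


def _stimulation_markdown(r: dict) -> str:
    lines = [f"# Stimulation experiment (seed {r['seed']})", ""]
    lines.append(
        "| age | LGN-VC delay (ms) | reliability (%) | 1-100 ms change (%) | "
        "100-250 ms change (%) | entrained at 20 Hz |"
    )
    lines.append("|---|---|---|---|---|---|")
    for age, d in r["ages"].items():
        o, t = d["opto"], d["train_20hz"]
        lines.append(
            f"| {age} | {o['lgn_vc_delay_ms']:.1f} | {o['reliability_pct']:.1f} | "
            f"{o['excitation_change_pct']:+.0f} | {o['inhibition_change_pct']:+.0f} | "
            f"{'yes' if t['entrained'] else 'no'} |"
        )
    lines.append("")
    return "\n".join(lines) + "\n"
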