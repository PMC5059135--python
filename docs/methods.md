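# Methods

This note documents the models, estimators and parameter choices behind
`spindleloop`: what the synthetic data emulate, how each quantity is
computed, which decisions were genuinely open, and what the package does
not attempt.

## 1. Synthetic spontaneous activity

### Generative model

Spontaneous thalamic (LGN) and cortical (VC) multi-unit activity is an
inhomogeneous Poisson process on a 1 ms rate grid, sampled by thinning.
The rate alternates between two regimes:

- **silence** — a constant baseline `base_rate_hz` (default 0.5 Hz;
  inter-wave firing is sparse but not zero);
- **active periods** — `wave_rate_hz · (1 + m·sin(2π f t + φ))` with
  `wave_rate_hz = 30 Hz`, modulation depth `m = 0.8`, `f` the age
  profile's spindle frequency, and a fresh uniform phase per period.

Active/silent durations are uniform draws from the age profile's
ranges. The defaults encode the developmental stages:

| profile | spindle freq | active | silent | opto latency | reliability | inhibition |
|---|---|---|---|---|---|---|
| P5_7   | 16.0 Hz | 1–5 s  | 10–60 s | 34.2 ms | 0.397 | no  |
| P9_11  | 23.1 Hz | 3–10 s | 10–60 s | 21.5 ms | 0.75  | no  |
| P13_14 | 23.1 Hz | 3–10 s | 5–30 s  | 20.0 ms | 0.924 | yes |

The P9–11 reliability is not tabulated anywhere as a single number; 0.75
was chosen once as the midpoint of the developmental trend and is not a
fitted value. Waves-within-active-period substructure (0.5–2 s waves in
clusters up to ~10 s) is deliberately **not** modelled: the analysis
operates on active periods as the unit, and the `wave_dur_s` /
`cluster_dur_s` fields are carried as metadata only.

### Manipulations

An acute silencing manipulation scales the targeted drive by
`residual_fraction` from `onset_s`:

- **retina** — the wave drive of both regions (the silent-period
  baseline is intrinsic and stays);
- **lgn** — thalamic output and, downstream, the cortical wave drive;
- **vc** — cortical firing, plus removal of the feedback share of the
  LGN wave drive: the LGN wave amplitude is multiplied by
  `1 − 0.8·(1 − residual)`, encoding that corticothalamic feedback
  supplies ~80% of thalamic wave firing. At P9–11 the modulation
  frequency simultaneously drops to the profile's no-feedback value
  (16.2 Hz) — the retina/thalamus-only rhythm; at P5–7 the frequency is
  unchanged (cortex does not yet pace the rhythm).

Every session's `meta` carries the generator's ground truth (active
periods, per-pulse logs, seeds), which is what the parameter-recovery
tests check estimators against.

### What the generator does *not* emulate

No biophysics (conductance-based cells), no retinotopy or eye-specific
lamination, no electrode drift, movement artifacts, anesthesia state
changes, or non-stationarities over the session. Poisson firing has no
refractoriness, so absolute counts at high instantaneous rates are
slightly optimistic. Consequently, passing tests demonstrate that the
*estimators* recover known structure at realistic rates and noise — not
that real recordings satisfy the generator's assumptions.

## 2. The corticothalamic feedback-loop model

A two-delay rate model with retinal drive `R(t)`:

    C(t) = max(0, a·L(t − d_LGN→VC))
    L(t) = max(floor, R(t)·(1 + g_fb·C(t − d_VC→LGN)) − g_inh·C(t − d_VC→LGN − d_inh))

integrated at `dt = 1 ms` (validation requires `dt ≤ min delay / 4`);
rates above a configurable ceiling abort with a diagnostic.

Delayed *positive* feedback alone does not oscillate — with constant
drive the loop is a pure amplifier with DC gain `1/(1 − G)`,
`G = R̄·g_fb·a`. Rhythm arises as **comb resonance**: broadband
fluctuations in the retinal drive pass through the transfer function
`|H(f)|² = 1/(1 − 2G·cos(2πfD) + G²)`, which peaks at multiples of the
inverse round-trip delay `1/D` (25 Hz for 20 + 20 ms). The default
drive is Gaussian noise smoothed to a 4 ms correlation scale around a
20 Hz mean; the smoothing rolls off the harmonics so the fundamental
dominates. Defaults `a = 0.25`, `g_fb = 0.16` give `G = 0.8`, i.e.
closed-loop rate ≈ 5× open loop — a calibration chosen to embody the
"~80% of thalamic firing comes from feedback" arithmetic, not a
measurement.

The inhibitory branch acts at an extra `d_inh = 40 ms`, so its total
loop delay (80 ms) is two resonance periods: it arrives in phase with
the excitatory return and cancels the resonance rather than merely
detuning it. `g_inh = 2` leaves ~2–6% of the 25 Hz power.

Spectral statements about the loop are made on the *deterministic* rate
trace (stored in `meta`), via a Welch periodogram with 2 s windows —
Poisson sampling noise is excluded by construction from the oracle.

## 3. Stimulation generators

**Optogenetic pulses.** Each 10 ms pulse triggers a cortical volley at
3.5 ms (400 Hz for 10 ms — direct channelrhodopsin activation, always
present) and, with probability `opto_reliability`, an LGN volley
(300 Hz for 30 ms) at the profile latency plus Gaussian jitter
(`opto_jitter_ms`). The volley amplitude is set so a responding trial
essentially always contains a spike (expected count ≈ 9), which is what
makes reliability a clean Bernoulli recovery problem.

With inhibition enabled (P13–14) the LGN rate is multiplied by 0.05 in
the 100–250 ms window after every pulse, and train pulses falling
inside an active suppression window fail to evoke a volley —
reproducing "responds to the first one or two pulses only".

During **trains**, latency jitter accumulates with pulse position:
`σ_j = sqrt(jitter² + (dispersion·j)²)`. The mature pathway
(dispersion ≈ 1 ms) keeps discrete volleys and entrains at 20 Hz; the
immature P5–7 pathway (dispersion 15 ms) still fires to later pulses
but with smeared, effectively tonic timing, so no 20 Hz component
builds up. This separation of *single-pulse* jitter (2 ms at P5–7,
keeping the measured onset near 34 ms) from *across-train* dispersion
is the package's mechanism for "firing without entrainment before
stage III"; it is a modelling choice, not a measured quantity.

**Flashes.** Each trial adds to a 2 Hz baseline a primary component
(0–200 ms, 80 Hz amplitude, 40 Hz early-gamma modulation, stimulus
phase-locked) and a secondary component (200–1000 ms, 40 Hz amplitude,
spindle-frequency modulation). In P13_14 mode the primary is a brief
(50 ms) non-oscillatory transient and the secondary shrinks to 3 Hz —
the post-eye-opening pattern. Stimulus onsets are at
`0, 30 s, 60 s, …` (one flash every 30 s).

## 4. Analysis estimators

**Events / continuity.** Maximal runs of spikes with every adjacent ISI
strictly below 500 ms ("less than" read literally; a tie at exactly
0.5 s breaks the run — configurable). Event span is [first spike, last
spike] with no padding; continuity counts event time only, over the
full supplied span (crop beforehand to exclude stimulation epochs).

**MUA spectra.** Mean-subtracted 1 ms counts → biased autocorrelation
to a 1 s maximum lag (0.5 Hz resolution, enough to resolve the 2–55 Hz
analysis band) → Hann taper over lags (suppresses truncation ripple) →
FFT, real part clipped at zero (warning if the clipped mass exceeds 1%
of the peak). Restriction to detected events is available by
accumulating within-segment autocovariances; the default uses the full
span. The autocorrelation spectrum of a Poisson train is already flat,
so the multiply-by-frequency compensation is **off** by default on this
pathway; it is **on** for multitaper LFP spectra, which do carry the
1/f background.

**LFP spectra.** Slepian multitapers, time-bandwidth 3 with 5 tapers,
non-overlapping fixed windows (2 s spontaneous / 0.3 s evoked),
averaged across windows, then ×f compensation.

**Post-processing.** Linear interpolation in log-frequency onto a
geometric grid (2–100 Hz, 60 points), then division by mean 2–55 Hz
power (in-band mean exactly 1). Evoked windows are 0.3 s, limiting
native resolution to ~3.3 Hz, so their grid and normalization band
start at 4 Hz. Peaks are the in-band argmax (ties → lower frequency),
flagged low-confidence when max/median < 1.5.

**PSTH and onset.** Trial-pooled counts over half-open 1 ms bins,
divided by trials × bin width; trials whose analysis window is not
fully in-span are dropped. Onset = first post-stimulus bin where the
2 ms-Gaussian-smoothed PSTH exceeds baseline mean + 3 SD for 3
consecutive bins, then refined on the raw PSTH: starting 5 ms before
the smoothed crossing, the onset is the first bin exceeding threshold
together with its successor. The refinement exists because smoothing
leaks a strong volley ~3 ms backwards, and the two-bin rule stops
single noise spikes from pulling the onset early; with it, latencies of
20–34 ms are recovered within ±2 ms from 100 trials. The onset
criterion itself (3 SD, 3 bins) is this package's convention — the
underlying experiments define none — and is computed on the population
PSTH (the per-trial alternative is noted but not implemented).

**Reliability.** Among trials with ≥ 1 cortical spike within 30 ms of
the pulse, the fraction with ≥ 1 LGN spike in the 1–100 ms excitation
window. Baseline firing inside that window inflates the estimate by
roughly `(1 − r)·(1 − e^{−λ·0.099})`; at the default 2 Hz baseline
this is ≈ 2 percentage points at r = 0.9 — negligible for the
developmental contrasts, but recovery tests of the Bernoulli parameter
use a 0.5 Hz baseline fixture.

**Entrainment.** Per-pulse response probability (≥ 1 LGN spike within
the excitation window truncated to one inter-pulse interval) plus the
spectral peak of the train-aligned PSTH over the train span + 100 ms
(the tail captures the last volley and sharpens the frequency grid to
~2.9 Hz for a five-pulse 20 Hz train). "Entrained" requires the peak
within one bin of the train frequency **and** mean pulse-3..n
probability ≥ half of pulse 1's.

## 5. Statistics

- **Wilcoxon signed-rank**: exact distribution for ≤ 25 nonzero
  differences (the experiments' regime is n = 6, where one-signed data
  give p = 2/2⁶ = 0.03125); zero differences dropped; all-zero input
  returns p = 1 with a flag.
- **Two-sample KS** with per-sample Dvoretzky–Kiefer–Wolfowitz 95%
  bands, `ε = sqrt(ln(2/α)/(2n))`.
- **Kruskal–Wallis** is exposed as a thin contract over the standard
  implementation.
- **Permutation spectrum test**: statistic = mean paired difference per
  frequency; null by sign flips of per-animal difference spectra —
  exhaustive 2ⁿ for n ≤ 12 (64 permutations at n = 6, exact by
  construction), seeded Monte Carlo above. Correction is pixel-based
  (max-statistic): threshold = (1 − α) "higher" quantile of the null
  max-|statistic| across bins, which yields the reported contiguous
  significant frequency ranges directly. A cluster-mass variant
  (cluster-forming at the per-frequency uncorrected quantile, null of
  max cluster mass) is available behind `correction="cluster"`.
  Permutation is at the animal level — the conservative unit for n = 6
  reporting; permuting spectral windows within animals would be the
  anti-conservative alternative.

Calibration at study scale (checked in the test suite): familywise
error ≤ 0.05 + 2 binomial SE over 500 null datasets; power ≥ 80% with
full selectivity below 10 Hz for a 40% power reduction confined to
20–28 Hz, at a per-frequency multiplicative spectrum noise of SD 0.15
(chosen once as representative scatter for n = 6 normalized spectra).

## 6. Pipeline and reproducibility

Experiments default to the study conditions: 6 animals × 2 paired
conditions × 20 min at 1 ms resolution. Per-animal seeds derive from
the master seed and the (animal, condition) indices via
`SeedSequence`, so adding animals never perturbs existing ones; one
generator stream per session, no global state. Reports (CSV + JSON +
markdown) contain no timestamps and use fixed float formatting:
identical seeds give byte-identical files. Calibration runs use the
sizes quoted above (500 null datasets, 50 seeds × 5 frequencies for
peak recovery, 100–200 trials for latency/reliability), which keep the
full suite and the acceptance script within a few minutes on one CPU.

## 7. Degenerate inputs and numerical conventions

All times are seconds from session start; bins are half-open
`[t, t + Δ)`. Empty spike trains produce empty event sets (continuity
0) and flagged empty spectra; zero-span sessions, zero baselines in
percent changes, windows outside the trial span, grids outside the
native frequency range, and double 1/f compensation all raise
`ValueError` rather than returning silent defaults. Channel selection
returns an explicit no-selection result when no channel meets its
criterion. Exact spike-time ties (probability zero, but possible after
merging) are broken by nudging one float ULP.

## 8. Known limitations

- The LFP synthesizer (band-limited noise + enveloped spindle
  oscillation) exists to exercise the multitaper pathway; it does not
  model laminar structure, current sinks, or realistic 1/f slopes.
- MUA extraction does no spike sorting and no artifact rejection,
  matching the multi-unit character of the analyses.
- The loop model is linear apart from floor/ceiling clipping; it makes
  no claim about conductances or the anatomical locus of inhibition.
- Phase or coherence between LGN and VC is out of scope (the recordings
  the analyses target are not topographically aligned), as are wavelet
  or Hilbert alternatives to the spectral pipeline.
- An NWB reader/writer is not included; sessions are plain CSV/JSON
  (plus float32 binary for LFP), and two-column delimited spike files
  are accepted directly.
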