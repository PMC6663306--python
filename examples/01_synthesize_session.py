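"""Synthesize a stimulation-mapping session and inspect its schedule.

Generates a 8-channel recording with a 30-s baseline and 12 stimulation
trials whose parameters are drawn uniformly from the 5 x 3 x 3 grid, then
prints the trial table. Intensity is amplitude x pulse frequency x
duration, the dose measure used by the cohort statistics.
"""

from stimnet import synth_session
from stimnet.stats import stim_intensity

rec, schedule, truth = synth_session(n_channels=8, n_trials=12, seed=7)

print(f"recording: {rec.n_channels} channels x {rec.n_samples} samples "
      f"@ {rec.fs:g} Hz ({rec.duration:.1f} s)")
print(f"baseline: {schedule.baseline_span[0]:g}-{schedule.baseline_span[1]:g} s, "
      f"{schedule.n_trials} trials, stim pair {schedule.trials[0].stim_pair}")
print(f"{'onset_s':>8} {'dur_s':>6} {'mA':>4} {'Hz':>6} {'intensity':>10}")
for t in schedule.trials:
    print(f"{t.onset:8.2f} {t.duration:6.2f} {t.amplitude:4.0f} "
          f"{t.pulse_frequency:6.0f} {stim_intensity(t):10.1f}")
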