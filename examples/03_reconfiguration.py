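"""Reconfiguration metrics on a single planted session.

Runs the full single-session pipeline (screening, referencing, epoching,
networks, surrogate baseline) on a session with a planted alpha/theta
coupling gain, and compares stimulation trials with surrogate baseline
trials per band: the planted band shows a clearly positive change in mean
node strength relative to surrogate, the other bands do not.
"""

from stimnet import RunConfig, run_session, session_band_tests
from stimnet.pipeline import planted_truth_kwargs

cfg = RunConfig(n_channels=8, n_trials=30)
result = run_session(cfg, seed=3, truth_kwargs=planted_truth_kwargs())

print(f"kept channels: {result.labels} (discarded: {result.discarded_channels})")
print(f"{'band':12s} {'stim dmean_k':>12} {'surr dmean_k':>12} {'p_adj':>8}")
table = session_band_tests(result, "delta_mean_k")
for _, row in table.iterrows():
    stim = result.session_mean(row["band"], "delta_mean_k")
    surr = result.session_mean(row["band"], "delta_mean_k", "surrogate")
    print(f"{row['band']:12s} {stim:12.4f} {surr:12.4f} {row['p_adj']:8.3g}")
print("the alpha/theta gain (+0.35, stim-routed) pushes the mean node "
      "strength up after stimulation while surrogate trials fluctuate near "
      "zero; a single 30-trial session rarely reaches Bonferroni-corrected "
      "significance on its own -- cross-session power comes from cohorts "
      "(see example 05).")
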