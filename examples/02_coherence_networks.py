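"""Band-specific coherence networks from a controlled coupling.

Couples one channel pair only in the high-gamma band and shows that the
multitaper coherence adjacency isolates the interaction in that band:
the coupled pair's high-gamma edge is strong while its alpha/theta edge
stays near the estimator's bias floor (~0.13-0.17 for uncoupled signals).
"""

import numpy as np

from stimnet import DEFAULT_BANDS, band_adjacency, synth_coupled_timeseries

coupling = {b.name: np.zeros((3, 3)) for b in DEFAULT_BANDS}
coupling["high_gamma"][0, 1] = coupling["high_gamma"][1, 0] = 0.9

rec = synth_coupled_timeseries(3, fs=500, duration=0.5, coupling=coupling,
                               noise_sd=1.0, seed=0)
nets = band_adjacency(rec.signal, rec.fs)

print("edge (ch00, ch01) coherence per band:")
for band in DEFAULT_BANDS:
    print(f"  {band.name:12s} [{band.lo:5.1f}-{band.hi:5.1f} Hz]  "
          f"{nets[band.name].A[0, 1]:.3f}")
print("high-gamma carries the planted 0.9 coupling (expected coherence "
      "~0.81 = c^2); other bands sit at the uncoupled floor.")
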