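"""Blended two-kernel median filtering of a noisy enhancement curve.

The filter applies a 3-sample median up to 5 minutes post-bolus, a 7-sample
median beyond 30 minutes, and a linear cross-fade in between, so the bolus
peak is barely smoothed while late-phase noise is strongly attenuated.
"""

import numpy as np

import liverdce as ld

rng = np.random.default_rng(0)
times = np.arange(-60.0, 3600.0, 10.0)
clean = 100.0 * (1 + 3 * (1 - np.exp(-np.clip(times, 0, None) / 300.0)))
noisy = clean + rng.normal(0, 5.0, times.size)
noisy[250] += 80.0  # isolated late-phase spike (t = 2440 s)

series = ld.SignalSeries(times=times, values=noisy, s0=100.0)
filtered = ld.blended_median_filter(series, ld.FilterSpec())

late = times >= 1800
print(f"late-phase residual SD, unfiltered: {np.std(noisy[late] - clean[late]):.2f}")
print(f"late-phase residual SD, filtered:   {np.std(filtered.values[late] - clean[late]):.2f}")
print(f"spike at t=2440 s: raw {noisy[250] - clean[250]:+.1f}, "
      f"filtered {filtered.values[250] - clean[250]:+.1f} (signal units above truth)")
# The 7-sample median removes the isolated spike entirely and roughly halves
# the late-phase noise, without touching the early enhancement rise.
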