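"""Convert an SPGR signal curve to gadolinium concentration and back.

Builds a small liver concentration ramp, renders it to signal with the dog
Gd-EOB-DTPA constants (T1(0) = 581 ms, r1 = 14.6 s^-1 mM^-1), then inverts
the chain and prints the worst round-trip error.
"""

import numpy as np

import liverdce as ld

acq = ld.AcquisitionParams(tr=0.005, flip_angle_deg=15.0, frame_interval=7.65,
                           bolus_time=76.5, n_baseline=10)
tc = ld.default_registry().lookup("dog", "Gd-EOB-DTPA", "liver")

times = np.arange(-76.5, 600.0, 7.65)
conc = np.clip(times, 0, None) / 600.0 * 2.0  # ramp to 2 mM
c = ld.ConcentrationSeries(times=times, values=conc, compartment="tissue")

signal = ld.concentration_to_signal(c, acq, tc.t1_0, tc.r1, s0=500.0)
r1, valid = ld.signal_to_relaxation(signal, acq, tc.t1_0)
back = ld.relaxation_to_tissue_concentration(r1, times, tc.r1_0, tc.r1, valid=valid)

print(f"peak concentration: {conc.max():.3f} mM")
print(f"peak signal enhancement: {ld.percent_enhancement(signal).max():.1f} %")
print(f"max round-trip error: {np.max(np.abs(back.values - conc)):.2e} mM")
# The round-trip error is at machine precision: the SPGR conversion chain is
# an exact analytic inverse pair.
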