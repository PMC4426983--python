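"""Simulate hypertonic-sucrose-evoked EPSCs for a range of fusion rates.

Builds the canonical parameter set, sweeps the maximal fusion rate constant
k2_max (the parameter hypertonicity acts on) and prints how peak current and
time-to-peak change — the signature concentration dependence of HS responses.
"""

import numpy as np

from rrpfit import MEPSCKernel, ModelParams, sweep_k2max

params = ModelParams()  # canonical set: k1D = 90 nC/s, k_minus1 = 0.16 1/s ...
kernel = MEPSCKernel()

traces = sweep_k2max(params, [0.5, 3.0, 5.0, 10.0], kernel, duration=8.0)

print("k2_max [1/s]   peak [nA]   time-to-peak [s]")
for tr, k2m in zip(traces, [0.5, 3.0, 5.0, 10.0]):
    i = int(np.argmin(tr.I))
    print(f"{k2m:12.1f} {-tr.I[i] / 1000:11.1f} {tr.t[i] - params.t0:16.3f}")

print(
    "\nLarger k2_max (stronger hypertonicity) gives bigger, earlier peaks while"
    "\nthe late steady current (set by the priming flux k1*D) stays the same."
)
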