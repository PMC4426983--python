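"""Fit a small population of synthetic cells and bootstrap parameter means.

Emulates a per-cell analysis: several noisy traces (one per 'cell'), each
fitted independently, then nonparametric bootstrap summaries of the fitted
parameters across cells — the way population means and CIs are reported.
"""

from rrpfit import (
    FitConfig, MEPSCKernel, ModelParams, bootstrap_means, fit_traces,
    synthesize_trace,
)

kernel = MEPSCKernel(sample_dt=2e-4)
cfg = FitConfig(n_starts=1, seed=0)
truth = ModelParams()

rrps, k2s = [], []
for cell in range(5):
    tr = synthesize_trace(truth, kernel, noise_sd=10.0, seed=100 + cell,
                          duration=6.0, dt=2e-4, mode="constant_k1D")
    res = fit_traces(tr, kernel, cfg)
    rrps.append(res.rrp)
    k2s.append({**res.shared, **res.per_trace[0]}["k2_max"])

for name, vals in [("RRP [nC]", rrps), ("k2_max [1/s]", k2s)]:
    bs = bootstrap_means(vals, n_resamples=10000, seed=1)
    print(f"{name:14s} mean {bs.mean:8.3f}  sd {bs.sd:8.4f}  "
          f"95% CI [{bs.ci95[0]:.3f}, {bs.ci95[1]:.3f}]")

print("\nThe CI is the percentile interval of 10,000 bootstrapped sample"
      "\nmeans across the 5 cells; with identical generating parameters it"
      "\nreflects pure fitting/noise variability.")
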