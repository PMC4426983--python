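# Methods

## Model and assumptions

`rrpfit` implements a minimal three-pool vesicle-state model for
Ca²⁺-independent, hypertonic-sucrose (HS)-evoked release: a depot pool *D*
feeds the readily releasable pool *R* with constant priming rate constant k₁
(no Ca²⁺-dependent priming; HS stimulation is Ca²⁺-independent), vesicles
unprime with k₋₁ and fuse with a time-dependent fusion rate constant k₂(t).
The fused pool *F* is tracked explicitly even though it does not feed back
on the dynamics; it provides cumulative-charge bookkeeping and makes mass
conservation (D + R + F constant) a testable invariant rather than an
assumption.  Pools are expressed in nC (charge equivalents of vesicle
counts), rates in s⁻¹, currents internally in nA with pA at the I/O
boundary.

HS action is modelled as a selective reduction of the fusion barrier: k₂
rises from a baseline (default 0, negligible against k₋₁) to k₂,max with
the delayed Gompertz-type onset k₂(t) = k₂,max·exp(−exp(−(t−t₀−t_del)/τ)).
The onset delay t_del absorbs the latency between solution exchange and the
response; τ sets the steepness of the rise.  Nothing is claimed about k₂
after stimulus offset: the time course holds its last value unless an
explicit offset time is given, at which k₂ returns instantaneously to
baseline.  Fits only ever use the window up to stimulus offset, so this
choice does not affect estimation.

A release-site variant (dR/dt = k₁D(S−R) − (k₋₁+k₂)R) is provided; with
constant k₁D it is mathematically equivalent to the unrestricted model
under k₁D → k₁DS, (k₋₁+k₂) → (k₁D+k₋₁+k₂), which the test suite verifies
pointwise.

Energetics: rate ratios translate to activation-energy changes through the
Arrhenius relation with a constant prefactor, ΔEₐ = R̄T·ln(k_b/k_a),
carried dimensionlessly in R̄T units (R̄ = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹,
default temperature 293 K) and converted to kcal/mol on demand.  The
prefactor A is never estimated; only energy differences are reported.
Positive values mean the barrier was lowered.  The allosteric Ca²⁺ ladder
k₂,ₙ = l₊·fⁿ is the same algebra with n identical per-ion steps ln f.

## Parameters that matter

| parameter | unit | default | role |
|---|---|---|---|
| k₁D | nC/s | 90 | priming flux; sets the late steady (refill) current |
| k₋₁ | s⁻¹ | 0.16 | unpriming; sets RRP = k₁D/k₋₁ and the recovery time 1/k₋₁ |
| k₂,max | s⁻¹ | 3.5 | maximal fusion rate; peak amplitude, time-to-peak, decay |
| t_del | s | 0.60 | onset delay; pure time shift of the response |
| τ | s | 0.20 | rise time constant; steepness of the rising phase |
| D | nC | 1000 | depot size; only identifiable when the refill phase sags |

The defaults are the canonical simulation set used throughout the tests and
examples, with Gaussian recording noise of mean 0 and σ = 10 pA added after
convolution.  The mEPSC kernel is a difference of exponentials (rise 0.5 ms,
decay 3 ms), truncated at ten decay constants and normalized to unit charge,
so pool units flow through the convolution unchanged; the physical quantal
charge (default 1.1×10⁻⁴ nC) is used only to convert charge to vesicle
counts.  Sampling defaults to 10 kHz.

## What the synthetic generator does and does not emulate

Synthetic traces are the model current (release rate convolved with the
unit-charge kernel) plus additive white Gaussian noise.  They emulate the
deterministic kinetics, units and noise floor of recorded HS responses.
They do not contain quantal granularity (release is a continuous rate),
receptor saturation or desensitization, baseline drift, line noise, or
solution-exchange artefacts.  Passing recovery tests therefore demonstrates
that the estimation machinery is correct and unbiased under the model's own
assumptions at realistic noise; it does not certify robustness to the
unmodelled artefacts of real recordings, which is what the quality screen
(onset, peak, decay-residual runs, steady-state bias) is for.  Note also
that with the canonical set the simulated currents are large relative to
σ = 10 pA, so recovery tests probe identifiability rather than noise limits.

## Numerical choices

- Public pool integration uses adaptive explicit Runge-Kutta 4(5)
  (`solve_ivp`, rtol 1e−8, atol 1e−10), interpolated onto the requested
  grid.  Mass conservation holds to roundoff (~1e−15 relative) because the
  pool derivatives sum to zero identically.
- The fitting loop uses an exponential-integrator fast path for the linear
  constant-k₁D RRP equation (exact for piecewise-constant rates on the
  sample grid, midpoint rule), numba-compiled when available; it agrees
  with the RK45 path to ~1e−7 relative on 5–10 kHz grids and is checked
  against it in the tests.
- Optimization runs in log₁₀ parameter space (rates span orders of
  magnitude) inside the bound box [1e−5, 1e6] applied on the natural scale;
  function-evaluation budgets default to 400 per fitted parameter.  The
  simplex's absolute `fatol` is anchored at 1e−9 of the initial cost so
  convergence is judged by parameter precision (`xatol`, default 1e−5 in
  log₁₀), not by an unreachable squared-error target on noisy data.
- Steady-state initialization (R(0) = k₁D/k₋₁) is refused for k₋₁ = 0; the
  caller must supply R(0) explicitly rather than having a value guessed.
- The delay-free single-exponential k₂ onset is used only inside the
  closed-form oracle for the no-replenishment solution; the full delayed
  onset is canonical everywhere else.
- Bootstrap CIs are percentile intervals of resampled means (default
  10,000 resamples); inputs are sorted first so summaries are
  order-invariant for a fixed seed.

## Open design choices made here

- RRP estimator C ("model_steady_state") integrates the
  replenishment-corrected current and adds the model-reconstructed unfused
  remainder and unpriming loss of the initial pool.  Subtracting the
  replenishment current alone recovers only the charge fused from the
  initially primed pool, which undershoots R(0) by the unpriming losses
  (~20% on the canonical set); the corrected estimator equals R(0) exactly
  on model-generated data and preserves the A ≤ C ≤ B ordering against the
  baseline-subtraction (A) and integrate-to-timepoint (B) estimators.
  Method B's "arbitrary post-peak time point" defaults to peak + 2 s.
- The depleted-fraction estimator behind depletion curves defaults to the
  steady-state definition 1 − R_end/R_start; a released-charge estimator
  (charge fused from the initially primed pool over a reference RRP, which
  may exceed 1 for an under-depleting reference) is selectable.
- The reference rate anchoring the energy-to-rate dose-response
  back-transform is a configuration input; no numeric default is asserted.
- The fit-quality screen replaces visual inspection with quantitative
  flags (onset within 0.2 s, peak within 15%, time-to-peak within 0.2 s,
  longest significant same-sign residual run ≤ 60% of the decay bins,
  steady-phase bias ≤ 10%).  Flagged fits are reported, never discarded.

## Known limitations

- Stage 1 identifies only the product k₁D.  The stage-2 split of k₁ and D
  (product pinned within 2% of the stage-1 value, all other parameters
  frozen) is identifiable only when the refill phase sags, and inherits any
  stage-1 bias: on strongly sagging synthetic traces the split lands within
  a factor ~1.5 of truth, not at it.  Flat-refill traces are flagged
  `depot_split_unidentifiable`.
- Simulation problem sizes in the test suite (6 s traces at 5 kHz, 21 fits
  per recovery family, 500 bootstrap replications at 1000 resamples) are
  deliberate scaled-down choices that preserve the tested contracts.
- No Ca²⁺-binding kinetics (only the fusion-rate ladder), no multi-pool
  (fast/slow) RRP extensions, no stochastic quantal release, no receptor
  nonlinearities, no ABF ingestion (CSV is the canonical trace format).
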