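# rrpfit

Kinetic modelling and fitting of synaptic responses to hypertonic sucrose
(HS).  `rrpfit` is for electrophysiologists and modellers who use HS
challenges to probe the readily releasable pool (RRP) of synaptic vesicles:
it simulates vesicle-pool dynamics and the resulting postsynaptic currents,
fits recorded (or synthetic) traces to recover priming, unpriming and fusion
rate constants plus RRP size, and converts fusion-rate changes into
activation-energy changes for the fusion barrier.

## Model

Vesicles move between a depot pool *D*, the readily releasable pool *R* and
a fused pool *F*:

    dD/dt = −k₁D + k₋₁R
    dR/dt =  k₁D − (k₋₁ + k₂(t))R
    dF/dt =  k₂(t)R

with priming rate constant k₁ (the priming flux k₁D is in nC/s; pools are
expressed in nC of charge equivalent), unpriming constant k₋₁ and fusion
rate constant k₂.  A hypertonic stimulus applied at t₀ raises k₂ from ~0 to
k₂,max with a delayed, smooth (Gompertz-type) onset

    k₂(t) = k₂,max · exp(−exp(−(t − t₀ − t_del)/τ)),   t ≥ t₀.

The pre-stimulus RRP is the priming/unpriming equilibrium R∞ = k₁D/k₋₁ (it
is derived from the fit, never a fit parameter), the post-stimulus RRP
recovers as R(t) = (R_end − R∞)e^(−k₋₁t) + R∞, and the depleted RRP
fraction of a long stimulus approaches k₂,max/(k₋₁ + k₂,max).  Measured
currents are modelled by convolving the release rate k₂(t)·R(t) with a
unit-charge canonical miniature-EPSC kernel (inward currents negative).

Because the fusion rate constant obeys the Arrhenius relation
k₂ = A·exp(−Eₐ/R̄T) with constant prefactor A, a rate change maps to a
barrier change ΔEₐ = R̄T·ln(k₂,after/k₂,before): additive effects on the
fusion barrier are multiplicative on release rates, which is how independent
modulators of fusion combine supralinearly.  The same algebra generates the
allosteric Ca²⁺-sensor ladder k₂,ₙ = l₊·fⁿ.

Fitting follows a two-stage scheme: the constant-priming-flux model (only
the R equation, k₁D one constant) is fit to the stimulus window by summed
squared error, with an optional global stage (simulated annealing or
differential evolution, bounds 10⁻⁵–10⁶) seeding a Nelder-Mead simplex with
multi-start restarts; a second stage can split k₁ and D from the sag of the
refill phase.  Joint fits of several concentrations share k₁D and k₋₁ while
k₂,max, t_del and τ stay free per trace.

## Worked example

`python examples/fit_synthetic_trace.py` generates a 6 s synthetic HS
response from the canonical parameter set (k₁D = 90 nC/s, k₋₁ = 0.16 s⁻¹,
k₂,max = 3.5 s⁻¹, t_del = 0.6 s, τ = 0.2 s, D = 1000 nC) with 10 pA Gaussian
recording noise, fits it and prints:

```
parameter      truth     fitted
k1D            90.000    89.9992
k_minus1        0.160     0.1600
k2_max          3.500     3.5000
t_del           0.600     0.6000
tau             0.200     0.2000
derived RRP     562.5     562.50  nC
quality screen all_ok: True

RRP estimators [nC]:  baseline-subtraction 459  integrate-to-timepoint 697  model-corrected 562
```

All five identifiable parameters are recovered, the RRP follows from
R∞ = k₁D/k₋₁, and the three RRP estimators show the expected ordering:
subtracting the steady current underestimates (459 nC), integrating to a
fixed post-peak time overestimates (697 nC), and the model-based
replenishment correction recovers the true initial pool (562 nC).

Other examples: `simulate_hs_response.py` (concentration-series sweep of
k₂,max), `depletion_vs_kinetics.py` (depleted fraction vs release kinetics),
`energy_landscape.py` (Arrhenius conversions and the Ca²⁺ ladder),
`population_bootstrap.py` (per-cell fits and bootstrap summaries).  A thin
CLI wraps the same API: `rrpfit simulate|fit|analyze|bootstrap|demo`.

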