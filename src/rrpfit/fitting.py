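"""Least-squares estimation of vesicle-state-model parameters from traces.

The procedure mirrors the two-stage scheme used for HS-evoked responses:

* stage 1 fits the constant-priming-flux model (only the RRP equation is
  integrated, with the priming flux k1*D treated as one constant) to the
  current in the stimulus window, minimizing the summed squared error
  between model prediction and data, optionally with a global stage
  (simulated annealing or differential evolution) followed by a local
  Nelder-Mead simplex from the global optimum, with multi-start restarts;
* stage 2 (:func:`refine_depot`) optionally re-fits k1 and D separately with
  everything else fixed and their product pinned to the stage-1 value, using
  the full two-pool system, to capture a sagging refill phase.

Several traces (e.g. a submaximal and a maximal concentration from the same
cell) can be fit jointly: priming and unpriming parameters are shared while
k2_max, t_del and tau remain free per trace, and the per-trace squared
errors are summed.  The RRP is never a fit parameter; it is derived post hoc
from the steady-state relation R = k1*D/k_minus1 at k2 = 0.

Optimization runs in log10 parameter space (rates span several orders of
magnitude) with bounds applied on the natural scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import differential_evolution, dual_annealing, minimize

from . import model
from ._fastsim import rrp_constant_k1D
from .params import ModelParams
from .synthesis import PA_PER_NA, MEPSCKernel, Trace, release_rate_to_current

logger = logging.getLogger(__name__)

#: Parameters the stage-1 (constant-k1D) model exposes.
STAGE1_PARAMS = ("k1D", "k_minus1", "k2_max", "t_del", "tau")


@dataclass
class FitConfig:
    """Configuration of the trace-fitting procedure.

    ``bounds`` default to the wide box [1e-5, 1e6] applied to every
    parameter on its natural scale; ``max_iter_per_param`` caps both
    iterations and function evaluations per fitted parameter.
    """

    fit_window: Optional[tuple[float, float]] = None
    shared_params: tuple[str, ...] = ("k1D", "k_minus1")
    free_per_trace: tuple[str, ...] = ("k2_max", "t_del", "tau")
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    max_iter_per_param: int = 400
    global_method: str = "none"  # {"annealing", "evolutionary", "none"}
    n_starts: int = 10
    seed: Optional[int] = None
    baseline_subtract: bool = True
    default_bounds: tuple[float, float] = (1e-5, 1e6)
    xatol: float = 1e-5
    fatol: float = 1e-10

    def bounds_for(self, name: str) -> tuple[float, float]:
        lo, hi = self.bounds.get(name, self.default_bounds)
        if not lo < hi:
            raise ValueError(f"invalid bounds for {name}: {lo} >= {hi}")
        return lo, hi

    def param_names(self, n_traces: int) -> list[str]:
        names = [f"shared:{p}" for p in self.shared_params]
        for i in range(n_traces):
            names += [f"trace{i}:{p}" for p in self.free_per_trace]
        return names


@dataclass
class FitResult:
    """Outcome of a (joint) trace fit.

    ``shared`` holds the parameters common to all traces (at least the
    priming flux k1D and unpriming constant k_minus1); ``per_trace`` one
    dict per trace with its free parameters.  ``rrp`` is the derived
    pre-stimulus RRP k1D/k_minus1 in nC.  Stage 1 identifies only the
    product k1*D, so the ModelParams returned by :meth:`params_for` carry an
    arbitrary depot split unless :func:`refine_depot` ran.
    """

    shared: dict[str, float]
    per_trace: list[dict[str, float]]
    sse: float
    rrp: float
    n_evaluations: int
    converged: bool
    quality_flags: Optional[dict] = None
    stage2: Optional[dict] = None
    starts: list[float] = field(default_factory=list)

    def params_for(self, i: int = 0, D0: float = 1000.0,
                   t0: Optional[float] = None) -> ModelParams:
        v = {**self.shared, **self.per_trace[i]}
        return ModelParams(
            k1=v["k1D"] / D0,
            k_minus1=v["k_minus1"],
            k2_max=v["k2_max"],
            t0=v.get("t0", 0.5) if t0 is None else t0,
            t_del=v["t_del"],
            tau=v["tau"],
            D0=D0,
        )

    def to_dict(self) -> dict:
        return {
            "shared": self.shared,
            "per_trace": self.per_trace,
            "sse_pA2": self.sse,
            "rrp_nC": self.rrp,
            "n_evaluations": self.n_evaluations,
            "converged": self.converged,
            "quality_flags": self.quality_flags,
            "stage2": self.stage2,
        }


def _baseline(trace: Trace) -> float:
    pre = trace.I[trace.t < trace.stim_on]
    return float(pre.mean()) if pre.size else 0.0


def _window_mask(trace: Trace, config: FitConfig) -> np.ndarray:
    lo, hi = config.fit_window or (trace.stim_on, trace.stim_off)
    if lo < trace.t[0] - 1e-12 or hi > trace.t[-1] + 1e-12:
        raise ValueError("fit window lies outside the trace")
    return (trace.t >= lo) & (trace.t <= hi)


def predict_current(
    trace_t: np.ndarray,
    t0: float,
    values: dict[str, float],
    kernel: MEPSCKernel,
) -> np.ndarray:
    """Stage-1 model current (pA) on a trace's time grid.

    Simulates the constant-k1D RRP equation from the k2 = 0 steady state,
    convolves the release rate with the mEPSC kernel and scales to pA.
    """
    p = ModelParams(
        k1=values["k1D"] / 1000.0, D0=1000.0, k_minus1=values["k_minus1"],
        k2_max=values["k2_max"], t0=t0, t_del=values["t_del"], tau=values["tau"],
    )
    k2 = model.k2_time_course(p, trace_t)
    R0 = values["k1D"] / values["k_minus1"]
    dt = float(trace_t[1] - trace_t[0])
    R = rrp_constant_k1D(trace_t, k2, values["k1D"], values["k_minus1"], R0)
    return release_rate_to_current(k2 * R, kernel, dt) * PA_PER_NA


def cost(
    values_per_trace: Sequence[dict[str, float]],
    traces: Sequence[Trace],
    kernel: MEPSCKernel,
    config: Optional[FitConfig] = None,
) -> float:
    """Summed squared error (pA^2) of the stage-1 model against traces.

    Each trace's SSE is computed on its fit window (after baseline
    subtraction if configured) and the per-trace SSEs are added up.
    """
    config = config or FitConfig()
    if len(values_per_trace) != len(traces):
        raise ValueError("need one value dict per trace")
    total = 0.0
    for vals, tr in zip(values_per_trace, traces):
        mask = _window_mask(tr, config)
        data = tr.I - (_baseline(tr) if config.baseline_subtract else 0.0)
        pred = predict_current(tr.t, tr.stim_on, vals, kernel)
        r = data[mask] - pred[mask]
        total += float(r @ r)
    return total


class _Objective:
    """Packs/unpacks the log10 parameter vector and counts evaluations."""

    def __init__(self, traces, kernel, config):
        self.traces = traces
        self.kernel = kernel
        self.config = config
        self.n_shared = len(config.shared_params)
        self.n_free = len(config.free_per_trace)
        self.names = list(config.shared_params) + list(config.free_per_trace)
        self.n_eval = 0
        self.log_bounds = []
        for name in config.shared_params:
            lo, hi = config.bounds_for(name)
            self.log_bounds.append((np.log10(lo), np.log10(hi)))
        for _ in traces:
            for name in config.free_per_trace:
                lo, hi = config.bounds_for(name)
                self.log_bounds.append((np.log10(lo), np.log10(hi)))
        self.data = []
        for tr in traces:
            mask = _window_mask(tr, config)
            base = _baseline(tr) if config.baseline_subtract else 0.0
            self.data.append((tr.t, tr.stim_on, (tr.I - base), mask))

    @property
    def n_params(self) -> int:
        return self.n_shared + self.n_free * len(self.traces)

    def unpack(self, x: np.ndarray) -> list[dict[str, float]]:
        theta = 10.0 ** np.asarray(x, float)
        shared = dict(zip(self.config.shared_params, theta[: self.n_shared]))
        out = []
        for i in range(len(self.traces)):
            block = theta[self.n_shared + i * self.n_free:
                          self.n_shared + (i + 1) * self.n_free]
            out.append({**shared, **dict(zip(self.config.free_per_trace, block))})
        return out

    def __call__(self, x: np.ndarray) -> float:
        for xi, (lo, hi) in zip(x, self.log_bounds):
            if xi < lo or xi > hi:
                return 1e300
        self.n_eval += 1
        per_trace = self.unpack(x)
        total = 0.0
        for vals, (t, t0, data, mask) in zip(per_trace, self.data):
            pred = predict_current(t, t0, vals, self.kernel)
            r = data[mask] - pred[mask]
            total += float(r @ r)
        if not np.isfinite(total):
            return 1e300
        logger.debug("cost eval %d: sse=%.6g", self.n_eval, total)
        return total


def initial_guess(trace: Trace, config: Optional[FitConfig] = None) -> dict[str, float]:
    """Heuristic stage-1 starting values from trace features.

    Reads the steady (refill) current for the priming flux, the charge above
    the steady level for the RRP (hence k_minus1), the visible onset for
    t_del, and peak amplitude/time for k2_max and tau.  Deliberately rough:
    it only needs to land inside the simplex's basin of attraction.
    """
    config = config or FitConfig()
    mask = _window_mask(trace, config)
    t, sig = trace.t[mask], -(trace.I - _baseline(trace))[mask] / PA_PER_NA
    dt = trace.dt
    n_sm = max(int(0.02 / dt), 1)
    sm = np.convolve(sig, np.ones(n_sm) / n_sm, mode="same")
    pre = trace.I[trace.t < trace.stim_on]
    sigma = (pre.std() / PA_PER_NA) if pre.size > 10 else 0.0

    n_ss = max(int(0.1 * sm.size), 1)
    i_ss = float(np.median(sm[-n_ss:]))
    peak = float(sm.max())
    t_peak = float(t[int(np.argmax(sm))])
    thresh = max(5.0 * sigma, 0.05 * peak)
    above = np.nonzero(sm > thresh)[0]
    t_on = float(t[above[0]]) if above.size else float(t[0])

    k1D = max(i_ss, 1e-4)
    charge = float(np.trapezoid(np.clip(sm - i_ss, 0.0, None), t))
    rrp = max(charge, 10 * k1D * dt, 1e-3)
    k_minus1 = np.clip(k1D / rrp, 1e-4, 50.0)
    t_del = float(np.clip(t_on - trace.stim_on, 0.05, 5.0))
    tau = float(np.clip((t_peak - t_on) / 4.0, 0.02, 2.0))
    k2_max = float(np.clip(2.0 * peak / rrp, 0.05, 200.0))
    return {"k1D": float(k1D), "k_minus1": float(k_minus1), "k2_max": k2_max,
            "t_del": t_del, "tau": tau}


def _pack_guess(obj: _Objective, guesses: Sequence[dict[str, float]]) -> np.ndarray:
    config = obj.config
    x = []
    for name in config.shared_params:
        x.append(np.mean([g[name] for g in guesses]))
    for g in guesses:
        for name in config.free_per_trace:
            x.append(g[name])
    x = np.log10(np.asarray(x, float))
    lo = np.array([b[0] for b in obj.log_bounds])
    hi = np.array([b[1] for b in obj.log_bounds])
    return np.clip(x, lo + 1e-9, hi - 1e-9)


def fit_traces(
    traces: Sequence[Trace] | Trace,
    kernel: MEPSCKernel,
    config: Optional[FitConfig] = None,
    x0: Optional[Sequence[dict[str, float]]] = None,
) -> FitResult:
    """Fit the stage-1 model to one or several traces.

    An optional global stage (``config.global_method``: simulated annealing
    or differential evolution over the bounded box) seeds a Nelder-Mead
    simplex; ``config.n_starts`` perturbed restarts guard against local
    minima and the best solution is kept.  Deterministic for a fixed
    ``config.seed``.  ``x0`` overrides the heuristic initial guess.
    """
    if isinstance(traces, Trace):
        traces = [traces]
    if len(traces) == 0:
        raise ValueError("need at least one trace")
    config = config or FitConfig()
    obj = _Objective(traces, kernel, config)
    rng = np.random.default_rng(config.seed)
    budget = config.max_iter_per_param * obj.n_params

    guesses = list(x0) if x0 is not None else [initial_guess(tr, config) for tr in traces]
    x_init = _pack_guess(obj, guesses)

    if config.global_method == "annealing":
        res = dual_annealing(obj, bounds=obj.log_bounds, x0=x_init,
                             maxfun=budget, seed=int(rng.integers(2**31 - 1)),
                             no_local_search=True)
        x_init = res.x
    elif config.global_method == "evolutionary":
        res = differential_evolution(obj, bounds=obj.log_bounds,
                                     maxiter=max(budget // (15 * obj.n_params), 10),
                                     seed=int(rng.integers(2**31 - 1)),
                                     polish=False, tol=1e-8, init="sobol")
        x_init = res.x
    elif config.global_method != "none":
        raise ValueError(f"unknown global method {config.global_method!r}")

    # the simplex's fatol is absolute; anchor it to the attainable noise
    # floor so "converged" reflects parameter precision, not an impossible
    # squared-error target on noisy data
    fatol = max(config.fatol, 1e-9 * max(obj(x_init), 1.0))
    best_x, best_f, converged, start_costs = None, np.inf, False, []
    for start in range(max(config.n_starts, 1)):
        xs = x_init if start == 0 else x_init + rng.normal(0.0, 0.2, size=x_init.size)
        lo = np.array([b[0] for b in obj.log_bounds])
        hi = np.array([b[1] for b in obj.log_bounds])
        xs = np.clip(xs, lo + 1e-9, hi - 1e-9)
        res = minimize(obj, xs, method="Nelder-Mead",
                       options={"maxiter": budget, "maxfev": budget,
                                "xatol": config.xatol, "fatol": fatol,
                                "adaptive": True})
        start_costs.append(float(res.fun))
        if res.fun < best_f:
            best_x, best_f = res.x, float(res.fun)
            converged = bool(res.success)
    # polish the winner once more from its own optimum
    res = minimize(obj, best_x, method="Nelder-Mead",
                   options={"maxiter": budget, "maxfev": budget,
                            "xatol": 0.1 * config.xatol, "fatol": 0.1 * fatol,
                            "adaptive": True})
    if res.fun <= best_f:
        best_x, best_f = res.x, float(res.fun)
        converged = converged or bool(res.success)

    per_trace_full = obj.unpack(best_x)
    shared = {k: per_trace_full[0][k] for k in config.shared_params}
    per_trace = [{k: v[k] for k in config.free_per_trace} for v in per_trace_full]
    if "k1D" in shared and "k_minus1" in shared:
        rrp = shared["k1D"] / shared["k_minus1"]
    else:
        v = per_trace_full[0]
        rrp = v["k1D"] / v["k_minus1"]
    if not converged:
        logger.warning("fit did not formally converge (sse=%.4g)", best_f)
    return FitResult(shared=shared, per_trace=per_trace, sse=best_f, rrp=float(rrp),
                     n_evaluations=obj.n_eval, converged=converged,
                     starts=start_costs)


def refine_depot(
    fit: FitResult,
    traces: Sequence[Trace] | Trace,
    kernel: MEPSCKernel,
    config: Optional[FitConfig] = None,
    product_tolerance: float = 0.02,
) -> FitResult:
    """Stage-2 re-fit of k1 and D with everything else fixed.

    Runs the full two-pool system (depot depletion included) and optimizes
    the split of the stage-1 priming flux into k1 and D0, keeping their
    product within ``product_tolerance`` of the stage-1 value.  When the
    refill phase carries no sag (constant priming flux generated the data)
    the split is unidentifiable; the result is then flagged rather than
    trusted.
    """
    if isinstance(traces, Trace):
        traces = [traces]
    config = config or FitConfig()
    k1D_star = fit.shared.get("k1D", fit.per_trace[0].get("k1D"))
    tr = traces[0]
    mask = _window_mask(tr, config)
    base = _baseline(tr) if config.baseline_subtract else 0.0
    data = (tr.I - base)[mask]
    dt = tr.dt
    n_eval = 0

    def model_current(k1: float, D0: float, vals: dict[str, float]) -> np.ndarray:
        p = ModelParams(k1=k1, D0=D0, k_minus1=vals["k_minus1"],
                        k2_max=vals["k2_max"], t0=tr.stim_on,
                        t_del=vals["t_del"], tau=vals["tau"])
        traj = model.integrate_pools(p, float(tr.t[-1]), mode="depletable_D",
                                     t_eval=tr.t, rtol=1e-7, atol=1e-9,
                                     r0=k1D_star / vals["k_minus1"])
        return release_rate_to_current(traj.release_rate, kernel, dt) * PA_PER_NA

    vals = {**fit.shared, **fit.per_trace[0]}

    def sse_for(k1: float, D0: float) -> float:
        nonlocal n_eval
        n_eval += 1
        r = data - model_current(k1, D0, vals)[mask]
        return float(r @ r)

    def objective(x):
        logD0, rel = x
        if not (-2.0 <= logD0 <= 6.0) or abs(rel) > product_tolerance:
            return 1e300
        D0 = 10.0 ** logD0
        return sse_for(k1D_star * (1.0 + rel) / D0, D0)

    # reference: effectively non-depletable depot (no sag) on this window;
    # the depot must dwarf the released charge, not just the RRP
    ref_sse = sse_for(k1D_star / 1e12, 1e12)
    best = None
    for logD0 in (2.0, 3.0, 4.0):
        res = minimize(objective, np.array([logD0, 0.0]), method="Nelder-Mead",
                       options={"maxiter": 200, "maxfev": 200,
                                "xatol": 1e-4, "fatol": 1e-9, "adaptive": True})
        if best is None or res.fun < best.fun:
            best = res
    D0 = 10.0 ** best.x[0]
    k1 = k1D_star * (1.0 + best.x[1]) / D0
    # identifiability: how much would D deplete over the fitted window?
    window = (config.fit_window or (tr.stim_on, tr.stim_off))
    released = fit.rrp  # order of magnitude of charge drawn from D
    depletion = released / D0 if D0 > 0 else 0.0
    improvement = (ref_sse - best.fun) / ref_sse if ref_sse > 0 else 0.0
    flag = "ok" if (depletion > 0.02 and improvement > 1e-4) else "depot_split_unidentifiable"
    stage2 = {"k1": float(k1), "D0": float(D0), "k1D": float(k1 * D0),
              "sse_pA2": float(best.fun), "identifiability": flag,
              "sse_improvement_rel": float(improvement),
              "window": list(window)}
    return FitResult(shared={**fit.shared}, per_trace=[dict(v) for v in fit.per_trace],
                     sse=fit.sse, rrp=fit.rrp,
                     n_evaluations=fit.n_evaluations + n_eval,
                     converged=fit.converged, quality_flags=fit.quality_flags,
                     stage2=stage2, starts=list(fit.starts))


@dataclass
class QualityThresholds:
    """Tolerances of the automated fit-quality screen.

    Quantitative surrogate for visual inspection; a flagged fit is reported,
    never discarded automatically.
    """

    onset_tol_s: float = 0.2
    peak_rel_tol: float = 0.15
    ttp_tol_s: float = 0.2
    decay_run_frac: float = 0.6
    steady_rel_tol: float = 0.10
    n_bins: int = 40


def _onset_time(t: np.ndarray, sig: np.ndarray, sigma: float) -> float:
    peak = sig.max()
    thresh = max(5.0 * sigma, 0.05 * peak)
    above = np.nonzero(sig > thresh)[0]
    return float(t[above[0]]) if above.size else float(t[-1])


def quality_screen(
    fit: FitResult,
    trace: Trace,
    kernel: MEPSCKernel,
    config: Optional[FitConfig] = None,
    thresholds: Optional[QualityThresholds] = None,
    trace_index: int = 0,
) -> dict:
    """Screen a fit against the four features checked by eye in practice.

    (1) onset time of the fitted curve, (2) peak amplitude and time-to-peak,
    (3) systematic residual runs in the post-peak decay, (4) bias in the
    steady-state (refill) phase.  Returns a dict of per-feature booleans
    (True = passed) plus the measured discrepancies.
    """
    config = config or FitConfig()
    th = thresholds or QualityThresholds()
    mask = _window_mask(trace, config)
    base = _baseline(trace) if config.baseline_subtract else 0.0
    t = trace.t[mask]
    data = -(trace.I - base)[mask]
    vals = {**fit.shared, **fit.per_trace[trace_index]}
    pred = -predict_current(trace.t, trace.stim_on, vals, kernel)[mask]
    pre = trace.I[trace.t < trace.stim_on]
    sigma = float(pre.std()) if pre.size > 10 else 0.0
    n_sm = max(int(0.02 / trace.dt), 1)
    ker = np.ones(n_sm) / n_sm
    data_sm = np.convolve(data, ker, mode="same")

    onset_d = _onset_time(t, data_sm, sigma)
    onset_m = _onset_time(t, pred, sigma)
    onset_ok = abs(onset_m - onset_d) <= th.onset_tol_s

    i_pd, i_pm = int(np.argmax(data_sm)), int(np.argmax(pred))
    peak_d, peak_m = float(data_sm[i_pd]), float(pred[i_pm])
    peak_err = abs(peak_m - peak_d) / max(abs(peak_d), 1e-12)
    ttp_err = abs(float(t[i_pm]) - float(t[i_pd]))
    peak_ok = peak_err <= th.peak_rel_tol and ttp_err <= th.ttp_tol_s

    resid = data - pred
    t_end_decay = min(float(t[i_pd]) + 2.0, float(t[-1]))
    dmask = (t > t[i_pd]) & (t <= t_end_decay)
    decay_ok, run_frac = True, 0.0
    if dmask.sum() >= th.n_bins:
        bins = np.array_split(resid[dmask], th.n_bins)
        means = np.array([b.mean() for b in bins])
        sig_bin = sigma / np.sqrt(max(dmask.sum() // th.n_bins, 1))
        signs = np.where(np.abs(means) > max(3 * sig_bin, 0.02 * peak_d),
                         np.sign(means), 0.0)
        run = best = 0
        prev = 0.0
        for s in signs:
            run = run + 1 if (s != 0 and s == prev) else (1 if s != 0 else 0)
            prev = s
            best = max(best, run)
        run_frac = best / th.n_bins
        decay_ok = run_frac <= th.decay_run_frac

    n_ss = max(int(0.2 * t.size), 1)
    ss_bias = float(resid[-n_ss:].mean())
    ss_level = max(abs(float(data_sm[-n_ss:].mean())), 1e-12)
    ss_tol = max(th.steady_rel_tol * ss_level, 4 * sigma / np.sqrt(n_ss))
    steady_ok = abs(ss_bias) <= ss_tol

    flags = {
        "onset_ok": bool(onset_ok),
        "peak_ok": bool(peak_ok),
        "decay_ok": bool(decay_ok),
        "steady_state_ok": bool(steady_ok),
        "all_ok": bool(onset_ok and peak_ok and decay_ok and steady_ok),
        "metrics": {
            "onset_diff_s": float(onset_m - onset_d),
            "peak_rel_err": float(peak_err),
            "ttp_diff_s": float(ttp_err),
            "decay_run_frac": float(run_frac),
            "steady_bias_pA": ss_bias,
        },
    }
    return flags
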