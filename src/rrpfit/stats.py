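"""Derived release quantities and bootstrap statistics.

Covers the three RRP estimators used on HS responses, depleted-fraction and
peak-release-rate readouts, the spontaneous fusion rate constant, and
nonparametric bootstrap summaries across cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import model
from .fitting import FitConfig, FitResult, _baseline
from .params import ModelParams
from .synthesis import PA_PER_NA, Trace


@dataclass
class RRPEstimate:
    """One RRP size estimate (nC) with the method that produced it.

    ``vesicle_count`` is derived by dividing by the mEPSC charge when one is
    supplied.
    """

    method: str
    value: float
    vesicle_count: Optional[float] = None
    flags: tuple[str, ...] = ()


def _charge(t: np.ndarray, current_pA: np.ndarray) -> float:
    """Inward charge in nC: -integral of I dt, pA*s -> nC."""
    return float(-np.trapezoid(current_pA, t)) / PA_PER_NA


def rrp_estimates(
    trace: Trace,
    fit: FitResult,
    config: Optional[FitConfig] = None,
    integration_endpoint: float = 2.0,
    mepsc_charge: Optional[float] = None,
) -> tuple[RRPEstimate, RRPEstimate, RRPEstimate]:
    """RRP size by the three standard estimators, in nC.

    * ``baseline_subtraction`` subtracts the steady current at the end of the
      response as a baseline and integrates; it under-corrects nothing but
      removes genuine early release at the steady level, so it
      underestimates.
    * ``integrate_to_timepoint`` integrates the (pre-stimulus-corrected)
      current up to ``integration_endpoint`` seconds past the peak with no
      replenishment correction, so it overestimates.
    * ``model_steady_state`` subtracts the model-reconstructed replenishment
      current (release of newly primed vesicles) before integrating, then
      adds back the model-reconstructed unreleased remainder and unpriming
      loss of the initial pool; on model-generated data this recovers R(0).

    With ongoing replenishment the expected ordering is A <= C <= B.
    """
    config = config or FitConfig()
    lo, hi = config.fit_window or (trace.stim_on, trace.stim_off)
    mask = (trace.t >= lo) & (trace.t <= hi)
    t = trace.t[mask]
    I = (trace.I - _baseline(trace))[mask]
    flags: list[str] = []

    n_ss = max(int(0.1 * t.size), 1)
    i_ss = float(np.median(I[-n_ss:]))
    # steady phase sanity: the late current should be flat
    late_slope = abs(np.polyfit(t[-n_ss:], I[-n_ss:], 1)[0]) * (t[-1] - t[0])
    if late_slope > 0.5 * abs(i_ss):
        flags.append("no_steady_phase")
    a = RRPEstimate("baseline_subtraction", max(_charge(t, I - i_ss), 0.0),
                    flags=tuple(flags))

    n_sm = max(int(0.02 / trace.dt), 1)
    sm = np.convolve(-I, np.ones(n_sm) / n_sm, mode="same")
    t_peak = float(t[int(np.argmax(sm))])
    bmask = t <= min(t_peak + integration_endpoint, t[-1])
    b = RRPEstimate("integrate_to_timepoint", max(_charge(t[bmask], I[bmask]), 0.0))

    vals = {**fit.shared, **fit.per_trace[0]}
    p = ModelParams(k1=vals["k1D"] / 1000.0, D0=1000.0,
                    k_minus1=vals["k_minus1"], k2_max=vals["k2_max"],
                    t0=trace.stim_on, t_del=vals["t_del"], tau=vals["tau"])
    # decompose from stimulus onset: before it, priming balances unpriming
    # and the initially-primed pool is the steady-state RRP
    split = model.split_replenishment(p.replace(t0=0.0),
                                      float(t[-1] - trace.stim_on),
                                      t_eval=t - trace.stim_on)
    I_new_pA = split.I_new * PA_PER_NA
    # charge fused from the initially primed pool, measured on the corrected
    # current, plus the reconstructed unfused remainder and unpriming loss
    fused_old = _charge(t, I - I_new_pA)
    remainder = float(split.R_old[-1])
    unprimed = float(vals["k_minus1"] * np.trapezoid(split.R_old, t))
    c = RRPEstimate("model_steady_state", max(fused_old + remainder + unprimed, 0.0))

    if mepsc_charge:
        for est in (a, b, c):
            est.vesicle_count = est.value / mepsc_charge
    return a, b, c


def depleted_fraction(
    params: ModelParams,
    reference_rrp: float,
    pulse: float,
    dt: float = 1e-3,
) -> float:
    """Charge released from the initially primed pool over the reference RRP.

    Simulates the replenishment split for ``pulse`` seconds past onset and
    divides the charge fused from the initially primed vesicles by
    ``reference_rrp``.  May exceed 1 when the reference stimulus itself
    under-depletes (a submaximal reference).
    """
    if reference_rrp <= 0:
        raise ValueError("reference_rrp must be > 0")
    t_eval = np.arange(0.0, pulse + 1e-12, dt)
    split = model.split_replenishment(params.replace(t0=0.0), pulse, t_eval=t_eval)
    return float(split.F_old[-1] / reference_rrp)


def peak_release_rate(
    params: ModelParams,
    pulse: float,
    dt: float = 1e-3,
    reference_rrp: Optional[float] = None,
    mode: model.IntegrationMode = "constant_k1D",
) -> dict:
    """Maximum of the release-rate trajectory k2(t)*R(t) and its timing.

    Returns the peak rate in nC/s, the time-to-peak relative to stimulus
    onset (s), and the rate in pool fractions/s when ``reference_rrp`` is
    given (defaulting to the pre-stimulus RRP).  A flat trajectory (no
    stimulus) carries a ``no_peak`` flag.
    """
    duration = params.t0 + pulse
    t_eval = np.arange(0.0, duration + 1e-12, dt)
    traj = model.integrate_pools(params, duration, mode=mode, t_eval=t_eval)
    rate = traj.release_rate
    if rate.max() <= 0:
        return {"peak_rate_nC_per_s": 0.0, "time_to_peak_s": np.nan,
                "peak_rate_pool_per_s": 0.0, "flags": ("no_peak",)}
    i = int(np.argmax(rate))
    ref = reference_rrp if reference_rrp is not None else traj.R[0]
    return {
        "peak_rate_nC_per_s": float(rate[i]),
        "time_to_peak_s": float(traj.t[i] - params.t0),
        "peak_rate_pool_per_s": float(rate[i] / ref) if ref > 0 else np.nan,
        "flags": (),
    }


def spontaneous_rate_constant(
    mepsc_freq: float, rrp_charge: float, mepsc_charge: float
) -> float:
    """Resting fusion rate constant from spontaneous release (s^-1).

    Divides the mEPSC frequency by the number of vesicles in the RRP
    (rrp_charge / mepsc_charge).  Note this attributes all spontaneous
    events to the Ca2+-independent pathway and therefore overestimates the
    truly Ca2+-independent component: spontaneous Ca2+ fluctuations
    contribute an apparent rate on the order of 2-4e-4 s^-1.
    """
    if mepsc_freq <= 0 or rrp_charge <= 0:
        raise ValueError("mepsc_freq and rrp_charge must be > 0")
    if mepsc_charge <= 0:
        raise ValueError("mepsc_charge must be > 0")
    return mepsc_freq / (rrp_charge / mepsc_charge)


@dataclass
class BootstrapSummary:
    """Summary of a bootstrap distribution of sample means."""

    n_resamples: int
    mean: float
    sd: float
    ci95: tuple[float, float]

    def to_dict(self) -> dict:
        return {"n_resamples": self.n_resamples, "mean": self.mean,
                "sd": self.sd, "ci95_low": self.ci95[0], "ci95_high": self.ci95[1]}


def bootstrap_means(
    values: Sequence[float],
    n_resamples: int = 10000,
    seed: Optional[int] = None,
) -> BootstrapSummary:
    """Nonparametric bootstrap of the sample mean.

    Resamples the original values with replacement ``n_resamples`` times and
    reports the mean, standard deviation and percentile 95% CI of the
    resampled means.  Values are sorted before resampling so the summary is
    invariant to input order for a fixed seed.
    """
    vals = np.sort(np.asarray(values, float))
    if vals.size < 2:
        raise ValueError("need at least 2 values to bootstrap")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, vals.size, size=(n_resamples, vals.size))
    means = vals[idx].mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return BootstrapSummary(
        n_resamples=n_resamples,
        mean=float(means.mean()),
        sd=float(means.std(ddof=1)),
        ci95=(float(lo), float(hi)),
    )
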