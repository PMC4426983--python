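"""Synthetic postsynaptic current traces from model release rates.

A release-rate time course (nC/s) is convolved with a unit-charge canonical
miniature-EPSC waveform to yield the macroscopic EPSC; Gaussian white
recording noise is added after convolution.  Because the kernel integrates to
one, total charge is conserved through the convolution and pool units (nC)
flow through unchanged.  Release is treated as a continuous rate (no quantal
granularity), matching how the model itself is fit to data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import fftconvolve

from . import model
from ._fastsim import rrp_constant_k1D
from .params import ModelParams

#: nA -> pA
PA_PER_NA = 1000.0

#: Default sampling interval (s); 10 kHz is the typical acquisition rate.
DEFAULT_DT = 1e-4


@dataclass(frozen=True)
class MEPSCKernel:
    """Canonical miniature-EPSC waveform used as convolution kernel.

    Difference-of-exponentials shape exp(-t/decay) - exp(-t/rise), normalized
    so its discrete integral is one (a unit-charge density in 1/s).  The
    physical charge of one quantum, ``charge`` (nC), is carried separately
    and used only to convert pool charge to vesicle counts.
    """

    rise_tau: float = 0.5e-3
    decay_tau: float = 3e-3
    charge: float = 1.1e-4
    sample_dt: float = DEFAULT_DT

    def __post_init__(self) -> None:
        if not (self.decay_tau > self.rise_tau > 0):
            raise ValueError("require decay_tau > rise_tau > 0")
        if self.charge <= 0 or self.sample_dt <= 0:
            raise ValueError("charge and sample_dt must be > 0")

    def waveform(self, dt: Optional[float] = None, n_decay: float = 10.0) -> np.ndarray:
        """Discrete unit-area kernel sampled at ``dt`` (1/s units).

        Truncated at ``n_decay`` decay time constants; the omitted tail is
        below 5e-5 of the charge for the default ``n_decay``.
        """
        dt = self.sample_dt if dt is None else dt
        t = np.arange(0.0, n_decay * self.decay_tau, dt)
        w = np.exp(-t / self.decay_tau) - np.exp(-t / self.rise_tau)
        area = w.sum() * dt
        if area <= 0:
            raise ValueError("degenerate kernel")
        return w / area


@dataclass
class Trace:
    """Uniformly sampled time-current record.

    ``I`` is in pA, inward currents negative.  ``stim_on``/``stim_off`` mark
    the stimulus window; ``label`` tags the nominal sucrose concentration (M).
    """

    t: np.ndarray
    I: np.ndarray
    stim_on: float
    stim_off: float
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.I = np.asarray(self.I, float)
        if self.t.shape != self.I.shape or self.t.ndim != 1:
            raise ValueError("t and I must be 1-D arrays of equal length")
        if self.t.size < 2:
            raise ValueError("a trace needs at least two samples")
        dts = np.diff(self.t)
        if np.any(dts <= 0) or np.ptp(dts) > 1e-9:
            raise ValueError("trace must be uniformly sampled (<=1e-9 s jitter)")
        if not self.stim_on < self.stim_off:
            raise ValueError("require stim_on < stim_off")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def current_nA(self) -> np.ndarray:
        return self.I / PA_PER_NA


def release_rate_to_current(
    rate: np.ndarray, kernel: MEPSCKernel, dt: Optional[float] = None
) -> np.ndarray:
    """Convolve a release rate (nC/s) into an inward current (nA).

    I(t) = -(rate * kernel)(t); with the unit-charge kernel the integral of
    -I equals the total released charge (up to the kernel tail beyond the
    record end).
    """
    dt = kernel.sample_dt if dt is None else dt
    rate = np.asarray(rate, float)
    w = kernel.waveform(dt)
    out = fftconvolve(rate, w)[: rate.size] * dt
    # FFT roundoff can leave ~1e-16 negatives; a non-negative rate and kernel
    # guarantee a non-negative convolution
    if rate.size and rate.min() >= 0.0:
        out = np.clip(out, 0.0, None)
    return -out


def simulate_current(
    params: ModelParams,
    kernel: MEPSCKernel,
    duration: float,
    dt: float = DEFAULT_DT,
    mode: model.IntegrationMode = "depletable_D",
    fast: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless model EPSC on a uniform grid.

    Returns ``(t, I_nA)``.  ``fast=True`` uses the exponential-integrator
    path for the constant-k1D approximation (identical to the RK45 result to
    ~1e-7 relative); the depletable-depot mode always integrates the full
    two-pool system.
    """
    t = np.arange(0.0, duration + dt / 2, dt)
    if fast and mode == "constant_k1D":
        k2 = model.k2_time_course(params, t)
        _, R0 = model.initial_state(params)
        R = rrp_constant_k1D(t, k2, params.k1D, params.k_minus1, R0)
        rate = k2 * R
    else:
        traj = model.integrate_pools(params, duration, mode=mode, t_eval=t)
        rate = traj.release_rate
    return t, release_rate_to_current(rate, kernel, dt)


def synthesize_trace(
    params: ModelParams,
    kernel: MEPSCKernel,
    noise_sd: float = 10.0,
    seed: Optional[int] = None,
    duration: float = 8.0,
    dt: float = DEFAULT_DT,
    stim_off: Optional[float] = None,
    label: str = "",
    mode: model.IntegrationMode = "depletable_D",
) -> Trace:
    """Generate a synthetic HS-evoked EPSC trace.

    The noiseless model current is computed with :func:`simulate_current`
    and additive Gaussian white noise (mean 0, sd ``noise_sd`` in pA) is
    superimposed; identical seeds give identical traces.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    t, current_nA = simulate_current(params, kernel, duration, dt=dt, mode=mode)
    I = current_nA * PA_PER_NA
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        I = I + rng.normal(0.0, noise_sd, size=I.size)
    return Trace(
        t=t,
        I=I,
        stim_on=params.t0,
        stim_off=float(duration if stim_off is None else stim_off),
        label=label,
        meta={"seed": seed, "noise_sd_pA": noise_sd, "mode": mode,
              "params": params.to_dict()},
    )


def sweep_k2max(
    params: ModelParams,
    k2_values: Sequence[float],
    kernel: MEPSCKernel,
    duration: float = 8.0,
    dt: float = DEFAULT_DT,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> list[Trace]:
    """Trace family varying only the maximal fusion rate constant.

    Emulates a concentration series: larger k2_max gives larger, narrower
    peaks with shorter time-to-peak while the late steady-state (refill)
    current is set by the priming flux.
    """
    if len(k2_values) == 0:
        raise ValueError("k2_values must be non-empty")
    traces = []
    for i, k2m in enumerate(k2_values):
        p = params.replace(k2_max=float(k2m))
        s = None if seed is None else seed + i
        traces.append(
            synthesize_trace(p, kernel, noise_sd=noise_sd, seed=s,
                             duration=duration, dt=dt, label=f"k2max={k2m:g}")
        )
    return traces
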