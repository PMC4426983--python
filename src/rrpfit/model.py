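"""Vesicle-state model dynamics.

Three pools: a depot pool D of non-primed vesicles, the readily releasable
pool R of primed vesicles, and the fused pool F.  Priming (k1), unpriming
(k_minus1) and fusion (k2) connect them:

    dD/dt = -k1*D + k_minus1*R
    dR/dt =  k1*D - (k_minus1 + k2(t))*R
    dF/dt =  k2(t)*R

During a hypertonic-sucrose stimulus k2 rises from its (negligible) baseline
to k2_max with a delayed, smooth Gompertz-type onset.  F is integrated even
though it does not feed back on the dynamics: it provides cumulative released
charge and makes mass conservation (D + R + F constant) testable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Optional

import numpy as np
from scipy.integrate import solve_ivp

from .params import ModelParams, SiteModelParams

IntegrationMode = Literal["constant_k1D", "depletable_D"]


@dataclass
class PoolTrajectory:
    """Time courses of the three pools along one simulation.

    All pools in nC; `k2` is the fusion rate constant series (s^-1) on the
    same grid, so the release rate is ``k2 * R`` (nC/s = nA) and the modelled
    inward current is ``-k2 * R``.
    """

    t: np.ndarray
    D: np.ndarray
    R: np.ndarray
    F: np.ndarray
    k2: np.ndarray

    @property
    def release_rate(self) -> np.ndarray:
        """Fusion flux k2(t)*R(t) in nC/s (= nA)."""
        return self.k2 * self.R

    @property
    def total(self) -> np.ndarray:
        return self.D + self.R + self.F


def k2_time_course(
    params: ModelParams,
    t: np.ndarray,
    t_off: Optional[float] = None,
) -> np.ndarray:
    """Fusion rate constant k2(t) during hypertonic stimulation.

    Before stimulus onset ``t0`` the baseline value applies; from ``t0`` on
    the rate follows the delayed expo-exponential (Gompertz) onset

        k2(t) = k2_max * exp(-exp(-(t - t0 - t_del)/tau)),

    which is non-decreasing and saturates at ``k2_max``.  If ``t_off`` is
    given, k2 returns instantaneously to baseline for t > t_off (the model
    makes no claim about the true offset time course; fits only ever use the
    window up to stimulus offset).

    Parameters
    ----------
    params : ModelParams
    t : array
        Monotone increasing time grid (s).
    t_off : float, optional
        Stimulus offset time (s).

    Returns
    -------
    ndarray of k2 values (s^-1) on `t`.
    """
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("t must be a non-empty 1-D array")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing")
    if params.k2_max > 0 and params.tau <= 0:
        raise ValueError("tau must be > 0 when k2_max > 0")
    k2 = np.full_like(t, params.k2_baseline, dtype=float)
    on = t >= params.t0
    if params.k2_max > 0:
        arg = -(t[on] - params.t0 - params.t_del) / params.tau
        k2[on] = params.k2_max * np.exp(-np.exp(arg))
    else:
        k2[on] = 0.0
    if t_off is not None:
        k2[t > t_off] = params.k2_baseline
    return k2


def initial_state(params: ModelParams, r0: Optional[float] = None) -> tuple[float, float]:
    """Pre-stimulus (D, R) assuming k2 = 0 steady state.

    R(0) = k1*D0/k_minus1.  With k_minus1 = 0 the steady state is undefined
    and an explicit ``r0`` must be supplied.
    """
    if r0 is not None:
        return params.D0, float(r0)
    if params.k_minus1 <= 0:
        raise ValueError(
            "steady-state initialization requires k_minus1 > 0; "
            "pass r0 explicitly for k_minus1 = 0"
        )
    return params.D0, params.k1 * params.D0 / params.k_minus1


def steady_state_rrp(params: ModelParams, k2: float = 0.0) -> float:
    """Steady-state RRP size R_inf = k1*D0 / (k_minus1 + k2) in nC.

    With k2 = 0 (the pre-stimulus assumption used for RRP reporting) this is
    the dynamic priming/unpriming equilibrium.
    """
    denom = params.k_minus1 + k2
    if denom <= 0:
        raise ValueError("k_minus1 + k2 must be > 0 for a defined steady state")
    return params.k1 * params.D0 / denom


def steady_state_rrp_sites(params: SiteModelParams, k2: float = 0.0) -> float:
    """Steady-state RRP of the release-site variant.

    R_inf = k1*D0*S / (k1*D0 + k_minus1 + k2).
    """
    denom = params.k1 * params.D0 + params.k_minus1 + k2
    if denom <= 0:
        raise ValueError("degenerate denominator: k1*D0 + k_minus1 + k2 must be > 0")
    return params.k1 * params.D0 * params.S / denom


def integrate_pools(
    params: ModelParams,
    duration: float,
    mode: IntegrationMode = "depletable_D",
    t_eval: Optional[np.ndarray] = None,
    r0: Optional[float] = None,
    k2_fn: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> PoolTrajectory:
    """Integrate the pool dynamics with an adaptive RK45 solver.

    Parameters
    ----------
    params : ModelParams
    duration : float
        Simulated interval [0, duration] in s.
    mode : {"depletable_D", "constant_k1D"}
        ``depletable_D`` runs the full two-pool system; ``constant_k1D``
        freezes the priming flux at k1*D0 (the approximation used for the
        initial fit of a trace) and only integrates R.
    t_eval : array, optional
        Output grid; defaults to 1 ms sampling.
    r0 : float, optional
        Explicit initial RRP, required when k_minus1 = 0.
    k2_fn : callable, optional
        Override for the fusion-rate time course (used by oracle tests, e.g.
        the delay-free single-exponential onset); defaults to
        :func:`k2_time_course`.
    rtol, atol : float
        Solver tolerances (explicit Runge-Kutta of order 4/5, variable step).

    Returns
    -------
    PoolTrajectory
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if t_eval is None:
        t_eval = np.arange(0.0, duration + 1e-12, 1e-3)
    else:
        t_eval = np.asarray(t_eval, dtype=float)
    D_init, R_init = initial_state(params, r0=r0)

    if k2_fn is None:
        def k2_fn(tt):
            return k2_time_course(params, np.atleast_1d(tt))

    def k2_scalar(tt: float) -> float:
        return float(k2_fn(np.asarray([tt]))[0])

    if mode == "constant_k1D":
        k1D = params.k1 * params.D0

        def rhs(tt, y):
            k2 = k2_scalar(tt)
            R, F = y
            return [k1D - (params.k_minus1 + k2) * R, k2 * R]

        y0 = [R_init, 0.0]
    elif mode == "depletable_D":
        def rhs(tt, y):
            k2 = k2_scalar(tt)
            D, R, F = y
            return [
                -params.k1 * D + params.k_minus1 * R,
                params.k1 * D - (params.k_minus1 + k2) * R,
                k2 * R,
            ]

        y0 = [D_init, R_init, 0.0]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    sol = solve_ivp(
        rhs, (0.0, float(duration)), y0, method="RK45",
        t_eval=t_eval, rtol=rtol, atol=atol, dense_output=False,
    )
    if not sol.success:  # pragma: no cover - solver failure is exceptional
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    k2_series = np.asarray(k2_fn(sol.t), dtype=float)
    if mode == "constant_k1D":
        D = np.full_like(sol.t, D_init)
        R, F = sol.y
    else:
        D, R, F = sol.y
    return PoolTrajectory(t=sol.t, D=D, R=R, F=F, k2=k2_series)


def integrate_site_model(
    params: SiteModelParams,
    duration: float,
    t_eval: Optional[np.ndarray] = None,
    r0: Optional[float] = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> PoolTrajectory:
    """Integrate the release-site variant with constant priming flux k1*D0.

    dR/dt = k1*D0*(S - R) - (k_minus1 + k2(t))*R.  Initialized at the k2 = 0
    steady state (all-site equilibrium) unless ``r0`` is given.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if t_eval is None:
        t_eval = np.arange(0.0, duration + 1e-12, 1e-3)
    k1D = params.k1 * params.D0
    R_init = steady_state_rrp_sites(params, k2=0.0) if r0 is None else float(r0)

    def rhs(tt, y):
        k2 = float(k2_time_course(params, np.asarray([tt]))[0])
        R, F = y
        return [k1D * (params.S - R) - (params.k_minus1 + k2) * R, k2 * R]

    sol = solve_ivp(
        rhs, (0.0, float(duration)), [R_init, 0.0], method="RK45",
        t_eval=np.asarray(t_eval, float), rtol=rtol, atol=atol,
    )
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    k2_series = k2_time_course(params, sol.t)
    R, F = sol.y
    return PoolTrajectory(
        t=sol.t, D=np.full_like(sol.t, params.D0), R=R, F=F, k2=k2_series
    )


@dataclass
class ReplenishmentSplit:
    """Decomposition of the RRP into initially-primed and newly-primed parts.

    ``R_old`` decays from R(0) by unpriming and fusion only; ``R_new`` starts
    at zero and collects the priming flux.  Their sum equals R of the joint
    system (the dynamics are linear).  ``I_old``/``I_new`` are the respective
    current components in nA, inward-negative: I = -k2*(R_old + R_new).
    """

    t: np.ndarray
    R_old: np.ndarray
    R_new: np.ndarray
    I_old: np.ndarray
    I_new: np.ndarray
    F_old: np.ndarray
    F_new: np.ndarray

    @property
    def R(self) -> np.ndarray:
        return self.R_old + self.R_new

    @property
    def I(self) -> np.ndarray:
        return self.I_old + self.I_new


def split_replenishment(
    params: ModelParams,
    duration: float,
    t_eval: Optional[np.ndarray] = None,
    r0: Optional[float] = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> ReplenishmentSplit:
    """Separate depletion of the initial RRP from on-going replenishment.

    Integrates (with constant priming flux k1*D0)

        dR_old/dt = -(k_minus1 + k2)*R_old,       R_old(0) = R(0)
        dR_new/dt = k1*D0 - (k_minus1 + k2)*R_new, R_new(0) = 0

    together with the released charge from each component (F_old, F_new).
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if t_eval is None:
        t_eval = np.arange(0.0, duration + 1e-12, 1e-3)
    _, R_init = initial_state(params, r0=r0)
    k1D = params.k1 * params.D0

    def rhs(tt, y):
        k2 = float(k2_time_course(params, np.asarray([tt]))[0])
        R_old, R_new, F_old, F_new = y
        a = params.k_minus1 + k2
        return [-a * R_old, k1D - a * R_new, k2 * R_old, k2 * R_new]

    sol = solve_ivp(
        rhs, (0.0, float(duration)), [R_init, 0.0, 0.0, 0.0], method="RK45",
        t_eval=np.asarray(t_eval, float), rtol=rtol, atol=atol,
    )
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    k2_series = k2_time_course(params, sol.t)
    R_old, R_new, F_old, F_new = sol.y
    return ReplenishmentSplit(
        t=sol.t,
        R_old=R_old,
        R_new=R_new,
        I_old=-k2_series * R_old,
        I_new=-k2_series * R_new,
        F_old=F_old,
        F_new=F_new,
    )


def rrp_recovery(params: ModelParams, R_end: float, t) -> np.ndarray:
    """Post-stimulus RRP recovery toward the k2 = 0 steady state.

    R(t) = (R_end - R_inf) * exp(-k_minus1 * t) + R_inf, with R_inf the
    priming/unpriming equilibrium; 1/k_minus1 is the recovery time constant.
    """
    if params.k_minus1 <= 0:
        raise ValueError("rrp_recovery requires k_minus1 > 0")
    R_inf = steady_state_rrp(params, k2=0.0)
    t = np.asarray(t, dtype=float)
    return (R_end - R_inf) * np.exp(-params.k_minus1 * t) + R_inf
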