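"""Arrhenius transforms between fusion rate constants and activation energies.

The fusion rate constant obeys k2 = A * exp(-Ea / (R*T)) with a constant
prefactor A, so a change in activation energy maps to a rate ratio:

    dEa = R*T * ln(k2_after / k2_before).

Energies are carried dimensionlessly in multiples of R*T (R = 1.9872e-3
kcal/(mol K)) and converted to kcal/mol on demand.  Positive values mean the
fusion barrier was lowered (rate increased).  Additive barrier changes
compose multiplicatively on the rate, which is what makes independent
modulators of fusion supralinear in combination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

#: Gas constant in kcal/(mol K).
R_GAS_KCAL = 1.9872e-3

#: Default absolute temperature (K) for conversions.
DEFAULT_TEMPERATURE_K = 293.0


@dataclass(frozen=True)
class EnergyDelta:
    """An activation-energy change in R*T units at a stated temperature."""

    value: float
    temperature_K: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        if self.temperature_K <= 0:
            raise ValueError("temperature_K must be > 0")

    @property
    def kcal_per_mol(self) -> float:
        return self.value * R_GAS_KCAL * self.temperature_K


def delta_Ea_from_rates(
    k2_a: float, k2_b: float, temperature_K: float = DEFAULT_TEMPERATURE_K
) -> EnergyDelta:
    """Activation-energy change inferred from a rate-constant change a -> b.

    Returns ln(k2_b / k2_a) in R*T units; positive when the rate increased
    (barrier lowered), antisymmetric under swapping the arguments.
    """
    if k2_a <= 0 or k2_b <= 0:
        raise ValueError("rate constants must be > 0")
    return EnergyDelta(float(np.log(k2_b / k2_a)), temperature_K)


def rt_to_kcal(delta: EnergyDelta) -> float:
    """Convert an R*T-unit energy change to kcal/mol at its temperature."""
    return delta.kcal_per_mol


def apply_energy_deltas(k2_0: float, deltas: Sequence[float | EnergyDelta]) -> float:
    """Fusion rate constant after additive barrier changes (R*T units).

    k2 = k2_0 * exp(sum(deltas)); order-independent, and applying the summed
    delta once gives the same result.
    """
    if k2_0 < 0:
        raise ValueError("k2_0 must be >= 0")
    total = float(sum(d.value if isinstance(d, EnergyDelta) else float(d) for d in deltas))
    return k2_0 * float(np.exp(total))


@dataclass(frozen=True)
class AllostericLadder:
    """Fusion-rate ladder of a Ca2+-sensor with n bound ions.

    Each bound ion lowers the fusion barrier by the same amount, multiplying
    the basal rate ``l_plus`` by a factor ``f`` per ion: k2_n = l_plus * f**n.
    """

    l_plus: float
    f: float
    n_max: int = 5

    def __post_init__(self) -> None:
        if self.l_plus < 0:
            raise ValueError("l_plus must be >= 0")
        if self.f < 1:
            raise ValueError("f must be >= 1")
        if self.n_max < 0:
            raise ValueError("n_max must be >= 0")

    @property
    def delta_E_per_ion(self) -> float:
        """Barrier reduction per bound ion, ln(f), in R*T units."""
        return float(np.log(self.f))


def allosteric_rates(ladder: AllostericLadder) -> np.ndarray:
    """Fusion rate constants k2_n = l_plus * f**n for n = 0..n_max.

    Identical to applying n copies of the per-ion energy delta ln(f) to
    ``l_plus``.
    """
    n = np.arange(ladder.n_max + 1)
    return ladder.l_plus * ladder.f ** n


@dataclass
class DoseResponseFit:
    """Mono-exponential fit dE(M) = a*exp(-b*M) + c of energy vs concentration."""

    a: float
    b: float
    c: float
    covariance: Optional[np.ndarray] = None
    degenerate: bool = False
    temperature_K: float = DEFAULT_TEMPERATURE_K
    residuals: np.ndarray = field(default_factory=lambda: np.array([]))

    def predict(self, concentrations) -> np.ndarray:
        m = np.asarray(concentrations, float)
        return self.a * np.exp(-self.b * m) + self.c


def fit_energy_dose_response(
    concentrations: Sequence[float],
    deltas: Sequence[float | EnergyDelta],
    temperature_K: float = DEFAULT_TEMPERATURE_K,
) -> DoseResponseFit:
    """Least-squares mono-exponential fit of energy change vs concentration.

    Fits dE(M) = a*exp(-b*M) + c (R*T units, M in molar).  Requires at least
    three distinct concentrations.  Constant data leave b unidentifiable; the
    fit is then reported with ``degenerate=True`` (a=0, b=0, c=mean).
    """
    m = np.asarray(concentrations, float)
    y = np.asarray(
        [d.value if isinstance(d, EnergyDelta) else float(d) for d in deltas], float
    )
    if m.size != y.size:
        raise ValueError("concentrations and deltas must have the same length")
    if np.unique(m).size < 3:
        raise ValueError("need >= 3 distinct concentrations")
    if np.ptp(y) == 0.0:
        return DoseResponseFit(0.0, 0.0, float(y[0]), degenerate=True,
                               temperature_K=temperature_K,
                               residuals=np.zeros_like(y))

    def f(x, a, b, c):
        return a * np.exp(-b * x) + c

    a0 = y[np.argmin(m)] - y[np.argmax(m)]
    span = np.ptp(m) or 1.0
    try:
        popt, pcov = curve_fit(
            f, m, y, p0=[a0 if a0 != 0 else 1.0, 1.0 / span, y[np.argmax(m)]],
            maxfev=20000,
        )
    except RuntimeError as err:
        raise RuntimeError(f"dose-response fit did not converge: {err}") from err
    res = y - f(m, *popt)
    degenerate = not np.all(np.isfinite(pcov))
    return DoseResponseFit(*map(float, popt), covariance=pcov,
                           degenerate=degenerate, temperature_K=temperature_K,
                           residuals=res)


def dose_response_rates(
    fit: DoseResponseFit,
    concentrations: Sequence[float],
    reference_rate: float,
    reference_concentration: float,
) -> np.ndarray:
    """Transform an energy dose-response fit into k2_max(M).

    Anchors the curve at a stated reference rate: k2_max(M) =
    reference_rate * exp(dE(M) - dE(M_ref)), the Arrhenius back-transform
    with a constant prefactor.
    """
    if reference_rate <= 0:
        raise ValueError("reference_rate must be > 0")
    de = fit.predict(concentrations)
    de_ref = float(fit.predict([reference_concentration])[0])
    return reference_rate * np.exp(de - de_ref)


def export_dose_response(
    fit: DoseResponseFit,
    concentrations: Sequence[float],
    reference_rate: float,
    reference_concentration: float,
    path,
) -> None:
    """Write a dose-response table as CSV.

    Columns: concentration_M, delta_Ea_RT (fitted curve), k2_max_s (the
    Arrhenius back-transform anchored at the reference rate).
    """
    m = np.asarray(concentrations, float)
    de = fit.predict(m)
    k2 = dose_response_rates(fit, m, reference_rate, reference_concentration)
    with open(path, "w") as fh:
        fh.write("concentration_M,delta_Ea_RT,k2_max_s\n")
        for row in zip(m, de, k2):
            fh.write(",".join(f"{v:.10g}" for v in row) + "\n")


def asymmetric_energy_sem(k2_mean: float, k2_sem: float) -> float:
    """SEM of an energy estimate from a symmetric rate-domain SEM.

    Log-transforming a symmetric error bar k2 +/- sem gives asymmetric halves
    ln(1 + sem/k2) and -ln(1 - sem/k2); the larger magnitude of the two is
    reported (in R*T units).
    """
    if k2_mean <= 0 or k2_sem < 0:
        raise ValueError("k2_mean must be > 0 and k2_sem >= 0")
    if k2_sem >= k2_mean:
        return float("inf")
    upper = np.log1p(k2_sem / k2_mean)
    lower = -np.log1p(-k2_sem / k2_mean)
    return float(max(upper, lower))
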