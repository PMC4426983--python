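"""Parameter containers for the vesicle-state model.

Internal units are seconds for time, nC for pool sizes (charge equivalents of
vesicle numbers), s^-1 for rate constants and nA (= nC/s) for currents.  File
I/O accepts and emits pA; see :mod:`rrpfit.io`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass


@dataclass(frozen=True)
class ModelParams:
    """Kinetic parameters of the depot/RRP/fused three-pool model.

    The depot pool ``D`` feeds the readily releasable pool ``R`` with priming
    rate constant ``k1`` (so the priming flux is ``k1*D`` in nC/s); vesicles
    unprime with rate constant ``k_minus1`` and fuse with the time-dependent
    rate constant ``k2(t)``, which rises from ``k2_baseline`` to ``k2_max``
    after stimulus onset ``t0`` following a delayed Gompertz-type time course
    with delay ``t_del`` and rise time constant ``tau``.

    Parameters
    ----------
    k1 : float
        Priming rate constant (s^-1). ``k1 * D0`` is the priming rate in nC/s.
    k_minus1 : float
        Unpriming rate constant (s^-1).
    k2_max : float
        Maximal fusion rate constant during the stimulus (s^-1).
    t0 : float
        Stimulus onset time (s).
    t_del : float
        Delay of the fusion-rate onset relative to ``t0`` (s).
    tau : float
        Rise time constant of the fusion-rate onset (s).
    D0 : float
        Initial depot pool size (nC).
    k2_baseline : float
        Pre-stimulus (spontaneous) fusion rate constant (s^-1), default 0.
    temperature_K : float
        Absolute temperature (K) used for energy conversions.
    """

    k1: float = 0.09
    k_minus1: float = 0.16
    k2_max: float = 3.5
    t0: float = 0.5
    t_del: float = 0.60
    tau: float = 0.20
    D0: float = 1000.0
    k2_baseline: float = 0.0
    temperature_K: float = 293.0

    def __post_init__(self) -> None:
        for name in ("k1", "k_minus1", "k2_max", "tau", "D0", "k2_baseline"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.k2_max > 0 and self.tau <= 0:
            raise ValueError("tau must be > 0 when k2_max > 0")
        if self.t_del < 0:
            raise ValueError("t_del must be >= 0")
        if self.temperature_K <= 0:
            raise ValueError("temperature_K must be > 0")

    @property
    def k1D(self) -> float:
        """Priming rate k1*D0 (nC/s)."""
        return self.k1 * self.D0

    def replace(self, **changes) -> "ModelParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return {
            "k1": self.k1,
            "k_minus1": self.k_minus1,
            "k2_max": self.k2_max,
            "t0": self.t0,
            "t_del": self.t_del,
            "tau": self.tau,
            "D0": self.D0,
            "k2_baseline": self.k2_baseline,
            "temperature_K": self.temperature_K,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})

    @classmethod
    def from_json(cls, text_or_path) -> "ModelParams":
        try:
            d = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                d = json.load(fh)
        return cls.from_dict(d)


@dataclass(frozen=True)
class SiteModelParams(ModelParams):
    """Model variant with a fixed number of release sites ``S``.

    Priming is hampered when few free sites remain: dR/dt = k1*D*(S - R)
    - (k_minus1 + k2)*R.  With k1*D held constant this is mathematically
    equivalent to the unrestricted model under the substitution
    k1D -> k1*D*S and (k_minus1 + k2) -> (k1*D + k_minus1 + k2).
    """

    S: float = 1.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.S <= 0:
            raise ValueError("S must be > 0")

    def equivalent_unrestricted(self) -> ModelParams:
        """Unrestricted-model parameters with identical R dynamics.

        Maps the site model onto the plain model by folding the site
        occupancy factor into the rates: the effective priming flux becomes
        k1*D*S and the effective unpriming constant k1*D + k_minus1.
        """
        return ModelParams(
            k1=self.k1 * self.S,
            k_minus1=self.k1 * self.D0 + self.k_minus1,
            k2_max=self.k2_max,
            t0=self.t0,
            t_del=self.t_del,
            tau=self.tau,
            D0=self.D0,
            k2_baseline=self.k2_baseline,
            temperature_K=self.temperature_K,
        )
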