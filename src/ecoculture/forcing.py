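"""Climate forcing of the unperturbed carrying capacity K0(t).

The replenishment term of the resource equation relaxes the carrying
capacity K towards an unperturbed level K0.  Holding K0 constant gives the
autonomous model; modulating it sinusoidally,

    K0(t) = K0* [1 + kappa * cos(Omega * t)],

mimics slow, periodic climatic variability (wet/dry cycles on orbital time
scales).  ``kappa < 1`` keeps K0(t) strictly positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError

__all__ = ["ClimateForcing", "constant_forcing", "standard_climate_forcing"]

#: Default forcing angular frequency: one full cycle per 10 000 time units.
STANDARD_OMEGA = 2.0 * math.pi / 10_000.0


@dataclass(frozen=True)
class ClimateForcing:
    """Evaluable contract ``t -> K0(t)``.

    Parameters
    ----------
    kind:
        ``"constant"`` (K0(t) = K0_star) or ``"periodic"``.
    K0_star:
        Baseline unperturbed carrying capacity (same units as density).
    kappa:
        Fractional amplitude of the sinusoidal modulation, ``0 <= kappa < 1``.
    omega:
        Angular frequency of the modulation, radians per time unit.
    """

    kind: str = "constant"
    K0_star: float = 1.0
    kappa: float = 0.0
    omega: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "periodic"):
            raise ParameterError(f"unknown forcing kind {self.kind!r}")
        if self.K0_star <= 0:
            raise ParameterError("forcing.K0_star must be positive")
        if not (0.0 <= self.kappa < 1.0):
            raise ParameterError(
                "forcing.kappa must lie in [0, 1) to keep K0(t) positive"
            )
        if self.omega < 0:
            raise ParameterError("forcing.omega must be non-negative")
        if self.kind == "periodic" and self.omega == 0.0:
            raise ParameterError("periodic forcing requires omega > 0")

    def __call__(self, t):
        """Evaluate K0 at time(s) ``t`` (scalar or array)."""
        if self.kind == "constant":
            return self.K0_star * np.ones_like(np.asarray(t, dtype=float))
        t = np.asarray(t, dtype=float)
        return self.K0_star * (1.0 + self.kappa * np.cos(self.omega * t))

    @property
    def period(self) -> float:
        """Forcing period 2*pi/omega (inf for constant forcing)."""
        if self.kind == "constant" or self.omega == 0.0:
            return math.inf
        return 2.0 * math.pi / self.omega


def constant_forcing(K0_star: float = 1.0) -> ClimateForcing:
    """Constant carrying-capacity baseline (no climate variability)."""
    return ClimateForcing(kind="constant", K0_star=K0_star)


def standard_climate_forcing() -> ClimateForcing:
    """Sinusoidal forcing with K0*=1, kappa=0.5 and a 10 000-step period."""
    return ClimateForcing(
        kind="periodic", K0_star=1.0, kappa=0.5, omega=STANDARD_OMEGA
    )
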