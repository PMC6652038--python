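"""Model parameters for the delayed within-host infection model.

State variables: ``u`` uninfected target cells, ``w`` infected cells, ``v``
free virus, ``z`` CTL effector cells (all concentrations).  The dynamics are

    u' = s - f1(u,v) v - f2(u,w) w - d1 u
    w' = f1(u,v) v + f2(u,w) w - d2 w - p w z
    v' = k w - d3 v
    z' = c w(t - tau) - d4 z

with a single constant delay ``tau`` in the CTL activation term.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

from .errors import ConfigurationError
from .incidence import IncidenceSpec

__all__ = ["ModelParameters"]


@dataclass(frozen=True)
class ModelParameters:
    """All rate constants, the delay, and the two incidence specifications.

    Parameters
    ----------
    s
        Recruitment rate of uninfected cells (concentration/time).
    d1, d2, d3, d4
        Death rates of uninfected cells, infected cells, free virus and CTL
        cells (1/time).
    p
        CTL killing rate of infected cells (per concentration per time).
    k
        Virion production rate per infected cell (1/time).
    c
        CTL production rate per (delayed) infected cell (1/time).
    tau
        Immune-activation delay (time, >= 0).
    f1, f2
        Incidence specifications for virus-to-cell and cell-to-cell
        transmission.
    """

    s: float
    d1: float
    d2: float
    d3: float
    d4: float
    p: float
    k: float
    c: float
    tau: float
    f1: IncidenceSpec
    f2: IncidenceSpec

    def __post_init__(self) -> None:
        for name in ("s", "d1", "d2", "d3", "d4", "p", "k", "c"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"parameter {name} must be > 0")
        if self.tau < 0:
            raise ConfigurationError("delay tau must be >= 0")
        for name in ("f1", "f2"):
            if not isinstance(getattr(self, name), IncidenceSpec):
                raise ConfigurationError(f"{name} must be an IncidenceSpec")

    @property
    def u0(self) -> float:
        """Uninfected-cell level of the infection-free steady state, s/d1."""
        return self.s / self.d1

    def with_tau(self, tau: float) -> "ModelParameters":
        """Copy of these parameters with a different delay."""
        return dataclasses.replace(self, tau=tau)
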