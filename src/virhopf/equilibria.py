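"""Basic reproduction number and steady states.

The infection-free equilibrium is ``E0 = (s/d1, 0, 0, 0)``.  The basic
reproduction number splits into a virus-to-cell and a cell-to-cell component,

    R0 = k f1(u0, 0) / (d2 d3)  +  f2(u0, 0) / d2,

and a positive (infection) equilibrium ``E* = (u*, w*, v*, z*)`` exists, and
is unique, exactly when ``R0 > 1``.  At a steady state the linear equations
for virus and CTLs give ``v* = (k/d3) w*`` and ``z* = (c/d4) w*``, and adding
the first two model equations gives ``u* = [s - w*(d2 + (p c/d4) w*)]/d1``,
so everything reduces to a scalar root-finding problem for ``w*`` on
``(0, w_bar]``, where ``w_bar`` (the infected-cell level at which ``u*``
would hit zero) is the positive root of ``(p c/d4) w^2 + d2 w - s = 0``.
The scalar equation is the infected-cell balance

    G(w) = f1(u,v) v + f2(u,w) w - (d2 + (p c/d4) w) w = 0,

which satisfies ``G(0) = 0``, ``G'(0) = d2 (R0 - 1)`` and ``G(w_bar) < 0``,
and is strictly decreasing at each of its zeros — hence the unique root.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import ConsistencyError, DegenerateThresholdError
from .incidence import incidence_partials, incidence_value
from .model import ModelParameters
from .simulate import rhs

__all__ = [
    "R0Summary",
    "EquilibriumState",
    "basic_reproduction_number",
    "infection_free_equilibrium",
    "w_upper_bound",
    "equilibrium_gap",
    "equilibrium_gap_derivative",
    "find_positive_equilibrium",
]

#: width of the band around R0 = 1 reported as threshold-degenerate
R0_THRESHOLD_BAND = 1e-8
#: |G(w*)| acceptance tolerance, relative to the scale d2 * w_bar
GAP_TOLERANCE = 1e-12


@dataclass(frozen=True)
class R0Summary:
    """Basic reproduction number and its transmission-route decomposition."""

    r0: float
    virus_to_cell: float
    cell_to_cell: float


@dataclass(frozen=True)
class EquilibriumState:
    """A steady state of the model with residual diagnostics.

    ``residuals`` are the four right-hand sides evaluated at the state (with
    the lagged ``w`` equal to ``w`` — delays do not move equilibria).
    """

    u: float
    w: float
    v: float
    z: float
    kind: str  # "infection_free" | "positive"
    residuals: tuple[float, float, float, float]

    @property
    def state(self) -> tuple[float, float, float, float]:
        return (self.u, self.w, self.v, self.z)

    @property
    def max_residual(self) -> float:
        return max(abs(r) for r in self.residuals)


def basic_reproduction_number(params: ModelParameters) -> R0Summary:
    """R0 with its virus-to-cell and cell-to-cell components."""
    u0 = params.u0
    r0_v2c = params.k * incidence_value(params.f1, u0, 0.0) / (params.d2 * params.d3)
    r0_c2c = incidence_value(params.f2, u0, 0.0) / params.d2
    return R0Summary(r0=r0_v2c + r0_c2c, virus_to_cell=r0_v2c, cell_to_cell=r0_c2c)


def infection_free_equilibrium(params: ModelParameters) -> EquilibriumState:
    """The always-present equilibrium ``(s/d1, 0, 0, 0)``."""
    state = (params.u0, 0.0, 0.0, 0.0)
    return EquilibriumState(*state, kind="infection_free", residuals=rhs(state, 0.0, params))


def w_upper_bound(params: ModelParameters) -> float:
    """Largest admissible infected-cell level ``w_bar``.

    Positive root of ``(p c/d4) w^2 + d2 w - s = 0``, evaluated in the
    cancellation-free form ``2 s / (d2 + sqrt(d2^2 + 4 s p c / d4))``.
    """
    q = params.p * params.c / params.d4
    return 2.0 * params.s / (params.d2 + np.sqrt(params.d2**2 + 4.0 * params.s * q))


def _auxiliary_state(w: float, params: ModelParameters) -> tuple[float, float, float]:
    q = params.p * params.c / params.d4
    u = (params.s - w * (params.d2 + q * w)) / params.d1
    if u < 0.0:
        # u vanishes exactly at w = w_bar; round-off can push it below zero
        u = 0.0
    v = (params.k / params.d3) * w
    z = (params.c / params.d4) * w
    return u, v, z


def equilibrium_gap(w: float, params: ModelParameters) -> float:
    """Infected-cell balance ``G(w)`` whose positive root is ``w*``.

    Accepts ``w = 0`` by the continuous extension ``G(0) = 0``.
    """
    wbar = w_upper_bound(params)
    if w < 0 or w > wbar * (1.0 + 1e-12):
        raise ValueError(f"w={w} outside the admissible interval [0, {wbar}]")
    if w == 0.0:
        return 0.0
    u, v, _ = _auxiliary_state(w, params)
    q = params.p * params.c / params.d4
    f1 = incidence_value(params.f1, u, v)
    f2 = incidence_value(params.f2, u, w)
    return f1 * v + f2 * w - (params.d2 + q * w) * w


def equilibrium_gap_derivative(w: float, params: ModelParameters) -> float:
    """Analytic ``dG/dw`` (used for Newton polishing of the root)."""
    u, v, _ = _auxiliary_state(w, params)
    q = params.p * params.c / params.d4
    du = -(params.d2 + 2.0 * q * w) / params.d1
    dv = params.k / params.d3
    f1 = incidence_value(params.f1, u, v)
    f2 = incidence_value(params.f2, u, w)
    f1u, f1v = incidence_partials(params.f1, u, v)
    f2u, f2w = incidence_partials(params.f2, u, w)
    return (
        (f1u * du + f1v * dv) * v
        + f1 * dv
        + (f2u * du + f2w) * w
        + f2
        - params.d2
        - 2.0 * q * w
    )


def find_positive_equilibrium(
    params: ModelParameters, scan_points: int = 4096
) -> EquilibriumState | None:
    """Locate the unique positive equilibrium, or ``None`` when ``R0 < 1``.

    The root of ``G`` is bracketed by a dense scan of ``(0, w_bar)`` (which
    also guards the uniqueness guaranteed by the theory: several sign changes
    raise :class:`ConsistencyError`, surfacing hypothesis violations of
    custom incidence functions), solved by Brent's method and polished by
    Newton steps with the analytic derivative.

    Raises
    ------
    DegenerateThresholdError
        If ``|R0 - 1| <= 1e-8``; the threshold case is not analyzed.
    """
    r0 = basic_reproduction_number(params).r0
    if abs(r0 - 1.0) <= R0_THRESHOLD_BAND:
        raise DegenerateThresholdError(f"R0 = {r0} lies in the threshold band around 1")
    if r0 < 1.0:
        return None

    wbar = w_upper_bound(params)
    grid = np.linspace(0.0, wbar, scan_points)[1:]
    gaps = np.array([equilibrium_gap(w, params) for w in grid])

    nz = np.where(np.sign(gaps) != 0)[0]
    flips = np.where(np.diff(np.sign(gaps[nz])) != 0)[0]
    if len(flips) > 1:
        raise ConsistencyError(
            f"G has {len(flips)} sign changes on (0, w_bar); the model "
            "hypotheses guarantee a unique root — check the incidence functions"
        )

    if len(flips) == 1:
        lo = grid[nz[flips[0]]]
        hi = grid[nz[flips[0] + 1]]
    else:
        # root closer to 0 than the grid spacing: G'(0) = d2 (R0-1) > 0 and
        # the first grid point is already on the negative side
        lo, hi = wbar * 1e-15, grid[0]
        while equilibrium_gap(lo, params) <= 0.0:
            lo *= 10.0
            if lo >= hi:
                raise ConsistencyError("failed to bracket the positive equilibrium")

    w_star = brentq(
        equilibrium_gap, lo, hi, args=(params,), xtol=1e-14 * max(wbar, 1.0), rtol=8.9e-16
    )
    # Newton polish (Brent is already near machine precision; this guards the
    # residual tolerance on badly scaled parameter sets)
    for _ in range(2):
        g = equilibrium_gap(w_star, params)
        dg = equilibrium_gap_derivative(w_star, params)
        if dg == 0.0:
            break
        step = g / dg
        if not np.isfinite(step) or abs(step) > 0.1 * wbar:
            break
        w_star -= step

    scale = params.d2 * wbar
    gap = equilibrium_gap(w_star, params)
    if abs(gap) > GAP_TOLERANCE * scale:
        raise ConsistencyError(f"|G(w*)| = {abs(gap)} exceeds tolerance {GAP_TOLERANCE * scale}")

    u, v, z = _auxiliary_state(w_star, params)
    state = (u, w_star, v, z)
    return EquilibriumState(*state, kind="positive", residuals=rhs(state, w_star, params))
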