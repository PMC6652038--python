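"""Incidence (infection-rate) functions and their derivatives.

The model couples uninfected target cells to free virus through ``f1(u, v)``
(virus-to-cell transmission) and to infected cells through ``f2(u, w)``
(cell-to-cell transmission); the recruitment of infected cells is
``f1(u,v)*v + f2(u,w)*w``.  Four classical families are built in:

=====================  =======================================
bilinear               ``beta*u``                (mass action)
saturation             ``beta*u / (1 + a*y)``
beddington_deangelis   ``beta*u / (1 + a1*u + a2*y)``
hattaf_yousfi          ``beta*u / (1 + a1*u + a2*y + a3*u*y)``
=====================  =======================================

where ``y`` is the second argument (``v`` for f1, ``w`` for f2).  The
Hattaf-Yousfi family contains Beddington-DeAngelis (``a3 = 0``),
Crowley-Martin (``a3 = a1*a2``), saturation (``a1 = 0``) and bilinear
(``a1 = a2 = a3 = 0``) as special cases.

All families satisfy the standing biological hypotheses:

(H3) ``f(0, y) = 0`` for every ``y >= 0`` — no infection without targets;
(H4) ``df/du > 0`` and ``df/dy <= 0`` — more targets raise the per-capita
     rate, interference between infectious agents lowers it;
(H5) ``f(u, y) + y * df/dy >= 0`` — the total incidence ``f(u, y) * y`` is
     nondecreasing in ``y``.

`check_hypotheses` verifies the three numerically on a grid, which is the
supported way to admit a ``custom`` incidence into the analysis pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "FAMILIES",
    "IncidenceSpec",
    "incidence_value",
    "incidence_partials",
    "check_hypotheses",
    "HypothesisReport",
    "value_closure",
    "partials_closure",
]

FAMILIES = ("bilinear", "saturation", "beddington_deangelis", "hattaf_yousfi", "custom")

#: relative step for finite-difference fallbacks (cube root of eps is optimal
#: for central differences)
_FD_REL_STEP = 6.0e-6


@dataclass(frozen=True)
class IncidenceSpec:
    """One incidence family with its parameters.

    Parameters
    ----------
    family
        One of :data:`FAMILIES`.
    beta
        Transmission coefficient (per concentration per time).
    a
        Saturation constant of the ``saturation`` family (per concentration).
    a1, a2, a3
        Interference constants of the Beddington-DeAngelis / Hattaf-Yousfi
        families.
    value_fn, partials_fn
        For ``family="custom"``: ``value_fn(u, y) -> f`` and optionally
        ``partials_fn(u, y) -> (df_du, df_dy)``.  Without ``partials_fn``
        the partials fall back to central finite differences.
    """

    family: str
    beta: float = 0.0
    a: float = 0.0
    a1: float = 0.0
    a2: float = 0.0
    a3: float = 0.0
    value_fn: Callable[[float, float], float] | None = field(default=None, compare=False)
    partials_fn: Callable[[float, float], tuple[float, float]] | None = field(
        default=None, compare=False
    )

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(
                f"unknown incidence family {self.family!r}; expected one of {FAMILIES}"
            )
        for name in ("beta", "a", "a1", "a2", "a3"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"incidence parameter {name} must be >= 0")
        if self.family == "custom" and self.value_fn is None:
            raise ConfigurationError("custom incidence requires value_fn")

    # -- constructors -----------------------------------------------------
    @classmethod
    def bilinear(cls, beta: float) -> "IncidenceSpec":
        return cls("bilinear", beta=beta)

    @classmethod
    def saturation(cls, beta: float, a: float) -> "IncidenceSpec":
        return cls("saturation", beta=beta, a=a)

    @classmethod
    def beddington_deangelis(cls, beta: float, a1: float, a2: float) -> "IncidenceSpec":
        return cls("beddington_deangelis", beta=beta, a1=a1, a2=a2)

    @classmethod
    def hattaf_yousfi(cls, beta: float, a1: float, a2: float, a3: float) -> "IncidenceSpec":
        return cls("hattaf_yousfi", beta=beta, a1=a1, a2=a2, a3=a3)

    @classmethod
    def custom(
        cls,
        value_fn: Callable[[float, float], float],
        partials_fn: Callable[[float, float], tuple[float, float]] | None = None,
    ) -> "IncidenceSpec":
        return cls("custom", value_fn=value_fn, partials_fn=partials_fn)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        if self.family == "custom":
            raise ConfigurationError("custom incidence specs cannot be serialized")
        out: dict = {"family": self.family, "beta": self.beta}
        if self.family == "saturation":
            out["a"] = self.a
        elif self.family == "beddington_deangelis":
            out.update(a1=self.a1, a2=self.a2)
        elif self.family == "hattaf_yousfi":
            out.update(a1=self.a1, a2=self.a2, a3=self.a3)
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "IncidenceSpec":
        data = dict(data)
        family = data.pop("family", None)
        if family is None:
            raise ConfigurationError("incidence mapping lacks 'family'")
        allowed = {"beta", "a", "a1", "a2", "a3"}
        unknown = set(data) - allowed
        if unknown:
            raise ConfigurationError(f"unknown incidence parameters: {sorted(unknown)}")
        return cls(family, **data)


def _check_args(u: float, y: float) -> None:
    if u < 0 or y < 0:
        raise ValueError(f"incidence arguments must be nonnegative, got u={u}, y={y}")


def incidence_value(spec: IncidenceSpec, u: float, y: float) -> float:
    """Evaluate ``f(u, y)`` for the family in *spec*."""
    _check_args(u, y)
    fam = spec.family
    if fam == "bilinear":
        return spec.beta * u
    if fam == "saturation":
        return spec.beta * u / (1.0 + spec.a * y)
    if fam == "beddington_deangelis":
        return spec.beta * u / (1.0 + spec.a1 * u + spec.a2 * y)
    if fam == "hattaf_yousfi":
        return spec.beta * u / (1.0 + spec.a1 * u + spec.a2 * y + spec.a3 * u * y)
    return float(spec.value_fn(u, y))


def incidence_partials(spec: IncidenceSpec, u: float, y: float) -> tuple[float, float]:
    """Return ``(df/du, df/dy)`` at ``(u, y)``.

    Analytic for the named families; for ``custom`` the supplied callable or,
    failing that, second-order finite differences with step scaled to the
    argument magnitude (one-sided at the domain boundary).
    """
    _check_args(u, y)
    fam = spec.family
    if fam == "bilinear":
        return spec.beta, 0.0
    if fam == "saturation":
        den = 1.0 + spec.a * y
        return spec.beta / den, -spec.beta * u * spec.a / den**2
    if fam == "beddington_deangelis":
        den = 1.0 + spec.a1 * u + spec.a2 * y
        return spec.beta * (1.0 + spec.a2 * y) / den**2, -spec.beta * u * spec.a2 / den**2
    if fam == "hattaf_yousfi":
        den = 1.0 + spec.a1 * u + spec.a2 * y + spec.a3 * u * y
        du = spec.beta * (1.0 + spec.a2 * y) / den**2
        dy = -spec.beta * u * (spec.a2 + spec.a3 * u) / den**2
        return du, dy
    if spec.partials_fn is not None:
        du, dy = spec.partials_fn(u, y)
        return float(du), float(dy)
    f = spec.value_fn
    return (_fd_partial(lambda x: f(x, y), u), _fd_partial(lambda x: f(u, x), y))


def _fd_partial(g: Callable[[float], float], x: float) -> float:
    """Second-order finite difference of ``g`` at ``x >= 0``."""
    h = _FD_REL_STEP * (1.0 + abs(x))
    if x - h >= 0.0:
        return (g(x + h) - g(x - h)) / (2.0 * h)
    # one-sided second-order stencil at the boundary
    return (-3.0 * g(x) + 4.0 * g(x + h) - g(x + 2.0 * h)) / (2.0 * h)


# ---------------------------------------------------------------------------
# hypothesis checking


@dataclass(frozen=True)
class HypothesisReport:
    """Result of :func:`check_hypotheses`; failures are reported, not raised."""

    vanishes_at_zero: bool      # (H3)  f(0, y) = 0
    monotone: bool              # (H4)  df/du > 0, df/dy <= 0
    product_nondecreasing: bool  # (H5) f + y*df/dy >= 0
    partials_consistent: bool   # analytic partials agree with finite differences
    max_zero_violation: float
    max_sign_violation: float
    max_product_violation: float
    max_partial_discrepancy: float

    @property
    def passed(self) -> bool:
        return (
            self.vanishes_at_zero
            and self.monotone
            and self.product_nondecreasing
            and self.partials_consistent
        )


def _default_grid() -> tuple[np.ndarray, np.ndarray]:
    axis = np.concatenate(([0.0], np.logspace(-2, 4, 13)))
    uu, yy = np.meshgrid(axis, axis)
    return uu.ravel(), yy.ravel()


def check_hypotheses(
    spec: IncidenceSpec,
    grid: tuple[np.ndarray, np.ndarray] | None = None,
    zero_tol: float = 1e-9,
    fd_rtol: float = 1e-4,
) -> HypothesisReport:
    """Verify hypotheses (H3)-(H5) on a grid of nonnegative ``(u, y)`` pairs.

    ``zero_tol`` is the absolute tolerance for the equality in (H3); sign
    conditions in (H4)/(H5) use the same tolerance as slack.  The analytic
    partials are additionally compared against central finite differences
    (relative tolerance ``fd_rtol``, which absorbs the O(h^2) truncation of
    the difference stencil).
    """
    if grid is None:
        us, ys = _default_grid()
    else:
        us, ys = np.asarray(grid[0], float).ravel(), np.asarray(grid[1], float).ravel()

    max_zero = 0.0
    max_sign = 0.0
    max_prod = 0.0
    max_fd = 0.0
    for u, y in zip(us, ys):
        f = incidence_value(spec, u, y)
        du, dy = incidence_partials(spec, u, y)
        if u == 0.0:
            max_zero = max(max_zero, abs(f))
        else:
            max_sign = max(max_sign, -du)  # du must be > 0
        max_sign = max(max_sign, dy)       # dy must be <= 0
        max_prod = max(max_prod, -(f + y * dy))
        fd_du = _fd_partial(lambda x: incidence_value(spec, x, y), u)
        fd_dy = _fd_partial(lambda x: incidence_value(spec, u, x), y)
        scale = max(1e-300, abs(du), abs(fd_du))
        max_fd = max(max_fd, abs(du - fd_du) / scale)
        scale = max(abs(dy), abs(fd_dy))
        if scale > zero_tol:
            max_fd = max(max_fd, abs(dy - fd_dy) / scale)

    return HypothesisReport(
        vanishes_at_zero=max_zero <= zero_tol,
        monotone=max_sign <= zero_tol,
        product_nondecreasing=max_prod <= zero_tol,
        partials_consistent=max_fd <= fd_rtol,
        max_zero_violation=max_zero,
        max_sign_violation=max_sign,
        max_product_violation=max_prod,
        max_partial_discrepancy=max_fd,
    )


# ---------------------------------------------------------------------------
# specialized plain-float closures for the integrator hot loop


def value_closure(spec: IncidenceSpec) -> Callable[[float, float], float]:
    """Return a plain-Python ``f(u, y)`` closure for *spec*.

    Avoids dataclass attribute lookups and dispatch inside the DDE
    integrator's inner loop.
    """
    fam = spec.family
    if fam == "bilinear":
        b = spec.beta
        return lambda u, y: b * u
    if fam == "saturation":
        b, a = spec.beta, spec.a
        return lambda u, y: b * u / (1.0 + a * y)
    if fam == "beddington_deangelis":
        b, a1, a2 = spec.beta, spec.a1, spec.a2
        return lambda u, y: b * u / (1.0 + a1 * u + a2 * y)
    if fam == "hattaf_yousfi":
        b, a1, a2, a3 = spec.beta, spec.a1, spec.a2, spec.a3
        return lambda u, y: b * u / (1.0 + a1 * u + a2 * y + a3 * u * y)
    return spec.value_fn


def partials_closure(spec: IncidenceSpec) -> Callable[[float, float], tuple[float, float]]:
    """Return a ``(u, y) -> (df_du, df_dy)`` closure for *spec*."""
    return lambda u, y: incidence_partials(spec, u, y)
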