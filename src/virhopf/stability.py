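"""Linear stability and Hopf bifurcation analysis.

Linearizing the model at the positive equilibrium gives the transcendental
characteristic equation

    lambda^4 + A3 lambda^3 + A2 lambda^2 + A1 lambda + A0
        + (B2 lambda^2 + B1 lambda + B0) e^(-lambda tau) = 0,

whose coefficients are assembled from the equilibrium shorthands

    Q0 = f1_u v* + f2_u w*,   Q1 = f1_v v* + f1*,   Q2 = f2_w w* + f2*

(all partial derivatives evaluated at E*; Q_i >= 0 under the incidence
hypotheses).  At ``tau = 0`` the equation is a quartic handled by the
Routh-Hurwitz criterion.  For ``tau > 0``, purely imaginary roots
``lambda = i omega`` must satisfy ``F(omega^2) = 0`` where

    F(z) = z^4 + M3 z^3 + M2 z^2 + M1 z + M0

with the M-coefficients below; each positive root ``z = omega^2`` yields a
ladder of critical delays ``tau_j = [arccos(Fc) + 2 pi j]/omega`` (or the
reflected branch when ``sin(omega tau) < 0``), and the crossing direction of
the root pair is ``sign(d Re lambda / d tau) = sign F'(omega^2)``: +1 means
a destabilizing crossing (left-to-right), -1 a stabilizing one.  The smallest
rung over all ladders is the first stability loss; subsequent rungs encode
stability switches.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .equilibria import EquilibriumState, basic_reproduction_number, find_positive_equilibrium
from .errors import ConsistencyError
from .incidence import incidence_partials, incidence_value
from .model import ModelParameters

__all__ = [
    "E0Analysis",
    "CharCoefficients",
    "FCoefficients",
    "Crossing",
    "RouthHurwitz",
    "HopfSummary",
    "e0_eigen_analysis",
    "q_terms",
    "char_coefficients",
    "routh_hurwitz_tau0",
    "f_poly",
    "f_value",
    "positive_crossings",
    "critical_delays",
    "char_residual",
    "transversality",
    "hopf_summary",
]

#: |Im|/(1+|Re|) below which a quartic root counts as real
_REAL_ROOT_TOL = 1e-9
#: Re(z) above which a real root counts as positive
_POSITIVE_ROOT_TOL = 1e-12
#: normalized residual bound for (i*omega, tau_j) on the characteristic equation
_RESIDUAL_TOL = 1e-8
#: |F'(z)| below this (times the local derivative scale) is degenerate
_DEGENERATE_FPRIME_TOL = 1e-10


# ---------------------------------------------------------------------------
# infection-free equilibrium


@dataclass(frozen=True)
class E0Analysis:
    """Eigenvalues at the infection-free equilibrium and the verdict."""

    roots: tuple[complex, complex, complex, complex]
    r0: float
    verdict: str  # "stable" | "unstable" | "marginal"


def e0_eigen_analysis(params: ModelParameters) -> E0Analysis:
    """Eigenvalues at E0.

    Two factors are always ``-d1`` and ``-d4``; the remaining quadratic
    ``lambda^2 + (d2 + d3 - f2(u0,0)) lambda + d2 d3 (1 - R0)`` has roots
    with negative real parts iff ``R0 < 1`` (the delay does not enter: the
    CTL equation decouples at E0).
    """
    r0 = basic_reproduction_number(params).r0
    f20 = incidence_value(params.f2, params.u0, 0.0)
    quad = np.roots([1.0, params.d2 + params.d3 - f20, params.d2 * params.d3 * (1.0 - r0)])
    roots = (-params.d1 + 0j, -params.d4 + 0j, complex(quad[0]), complex(quad[1]))
    max_re = max(r.real for r in roots)
    if r0 < 1.0:
        verdict = "stable"
    elif r0 > 1.0:
        verdict = "unstable"
    else:
        verdict = "marginal"
    if verdict == "stable" and max_re >= 0:  # pragma: no cover - theory guard
        raise ConsistencyError("R0 < 1 but a root has nonnegative real part")
    return E0Analysis(roots=roots, r0=r0, verdict=verdict)


# ---------------------------------------------------------------------------
# characteristic coefficients at E*


def q_terms(eq: EquilibriumState, params: ModelParameters) -> tuple[float, float, float]:
    """The equilibrium combinations (Q0, Q1, Q2) of incidence partials."""
    if eq.kind != "positive":
        raise ValueError("Q-terms are defined at the positive equilibrium only")
    f1u, f1v = incidence_partials(params.f1, eq.u, eq.v)
    f2u, f2w = incidence_partials(params.f2, eq.u, eq.w)
    f1s = incidence_value(params.f1, eq.u, eq.v)
    f2s = incidence_value(params.f2, eq.u, eq.w)
    return (f1u * eq.v + f2u * eq.w, f1v * eq.v + f1s, f2w * eq.w + f2s)


@dataclass(frozen=True)
class CharCoefficients:
    """Coefficients of the transcendental characteristic equation at E*."""

    A3: float
    A2: float
    A1: float
    A0: float
    B2: float
    B1: float
    B0: float
    Q0: float
    Q1: float
    Q2: float

    def delay_free_quartic(self) -> np.ndarray:
        """Coefficients (descending) of the tau=0 quartic."""
        return np.array(
            [1.0, self.A3, self.A2 + self.B2, self.A1 + self.B1, self.A0 + self.B0]
        )

    def residual_at(self, lam: complex, tau: float) -> complex:
        """Characteristic function value at (lambda, tau)."""
        poly = lam**4 + self.A3 * lam**3 + self.A2 * lam**2 + self.A1 * lam + self.A0
        delay = (self.B2 * lam**2 + self.B1 * lam + self.B0) * np.exp(-lam * tau)
        return poly + delay


def char_coefficients(eq: EquilibriumState, params: ModelParameters) -> CharCoefficients:
    """Assemble the A-, B- and Q-coefficients at the positive equilibrium.

    The delay-free quartic factors as ``(lambda + d4)`` times the cubic from
    the (u, w, v) block, and the delay part is
    ``p w* c (lambda + d1 + Q0)(lambda + d3)``; both are expanded exactly.
    All seven leading coefficients are positive under the model hypotheses —
    a non-positive one raises :class:`ConsistencyError`.
    """
    if eq.kind != "positive":
        raise ValueError("characteristic coefficients require the positive equilibrium")
    d1, d2, d3, d4, p, k, c = (
        params.d1,
        params.d2,
        params.d3,
        params.d4,
        params.p,
        params.k,
        params.c,
    )
    q0, q1, q2 = q_terms(eq, params)
    dd = d2 + p * eq.z - q2  # effective infected-cell decay; > 0 at E*
    aa = d1 + q0
    x = dd * d3 - k * q1

    a3 = aa + dd + d3 + d4
    a2 = aa * (dd + d3 + d4) + d3 * d4 + d4 * dd + x + q0 * q2
    a1 = (aa + d4) * x + q0 * q2 * (d3 + d4) + k * q0 * q1 + aa * d4 * (dd + d3)
    a0 = d4 * (aa * x + d3 * q0 * q2 + k * q0 * q1)
    b2 = p * eq.w * c
    b1 = b2 * (d1 + d3 + q0)
    b0 = b2 * d3 * (d1 + q0)

    coef = CharCoefficients(a3, a2, a1, a0, b2, b1, b0, q0, q1, q2)
    for name in ("A3", "A2", "A1", "A0", "B2", "B1", "B0"):
        if not getattr(coef, name) > 0:
            raise ConsistencyError(
                f"characteristic coefficient {name} = {getattr(coef, name)} is not "
                "positive; the incidence hypotheses are violated at this equilibrium"
            )
    return coef


class RouthHurwitz(NamedTuple):
    """Routh-Hurwitz determinants for the tau=0 quartic."""

    H1: float
    H2: float
    stable: bool


def routh_hurwitz_tau0(coef: CharCoefficients) -> RouthHurwitz:
    """Stability of E* at tau = 0.

    With all coefficients positive, the quartic is Hurwitz iff
    ``H1 = A3(A2+B2) - (A1+B1) > 0`` and
    ``H2 = A3(A2+B2)(A1+B1) - A3^2(A0+B0) - (A1+B1)^2 > 0``.
    """
    a3 = coef.A3
    a2 = coef.A2 + coef.B2
    a1 = coef.A1 + coef.B1
    a0 = coef.A0 + coef.B0
    h1 = a3 * a2 - a1
    h2 = a3 * a2 * a1 - a3**2 * a0 - a1**2
    return RouthHurwitz(H1=h1, H2=h2, stable=(h1 > 0 and h2 > 0))


# ---------------------------------------------------------------------------
# imaginary-axis crossings


class FCoefficients(NamedTuple):
    """Coefficients of F(z) = z^4 + M3 z^3 + M2 z^2 + M1 z + M0, z = omega^2."""

    M3: float
    M2: float
    M1: float
    M0: float


def f_poly(coef: CharCoefficients) -> FCoefficients:
    """The squared-modulus polynomial whose positive roots are omega^2.

    F(omega^2) = |P(i omega)|^2 - |Q(i omega)|^2 where P is the delay-free
    quartic part and Q the delay part of the characteristic equation.
    """
    a3, a2, a1, a0 = coef.A3, coef.A2, coef.A1, coef.A0
    b2, b1, b0 = coef.B2, coef.B1, coef.B0
    return FCoefficients(
        M3=a3**2 - 2.0 * a2,
        M2=a2**2 + 2.0 * a0 - 2.0 * a1 * a3 - b2**2,
        M1=a1**2 - 2.0 * a2 * a0 + 2.0 * b2 * b0 - b1**2,
        M0=a0**2 - b0**2,
    )


def f_value(m: FCoefficients, z: float) -> float:
    return ((((z + m.M3) * z + m.M2) * z) + m.M1) * z + m.M0


def _f_derivative(m: FCoefficients, z: float) -> float:
    return ((4.0 * z + 3.0 * m.M3) * z + 2.0 * m.M2) * z + m.M1


def _lemma1_predicts_root(m: FCoefficients) -> bool | None:
    """Resolvent-cubic classification of whether F has a positive root.

    Returns ``None`` when the configuration is too close to a boundary case
    to classify reliably.
    """
    scale = max(1.0, abs(m.M3), abs(m.M2), abs(m.M1), abs(m.M0))
    if abs(m.M0) <= 1e-9 * scale:
        return None
    if m.M0 < 0:
        return True
    m1 = m.M2 / 2.0 - 3.0 * m.M3**2 / 16.0
    m0 = m.M3**3 / 32.0 - m.M3 * m.M2 / 8.0 + m.M1 / 4.0
    disc = (m0 / 2.0) ** 2 + (m1 / 3.0) ** 3
    # stationary points of F: real roots of the depressed cubic, shifted back
    crit = [y.real - m.M3 / 4.0 for y in np.roots([1.0, 0.0, m1, m0]) if abs(y.imag) < 1e-9]
    candidates = [z for z in crit if z > 0]
    if disc >= 0:
        # one real stationary point z1
        return bool(candidates and f_value(m, max(candidates)) <= 0)
    return bool(any(f_value(m, z) <= 0 for z in candidates))


@dataclass(frozen=True)
class Crossing:
    """A purely imaginary characteristic root candidate.

    ``delta`` is the transversality sign: +1 destabilizing, -1 stabilizing,
    0 degenerate (repeated root of F; excluded from Hopf claims).
    """

    omega: float
    z: float
    f_prime: float
    delta: int
    delays: np.ndarray = field(default=None, compare=False)


def positive_crossings(m: FCoefficients) -> list[Crossing]:
    """All crossing frequencies omega_i = sqrt(z) for positive roots z of F.

    Solved directly via the quartic's companion matrix (`numpy.roots`); the
    resolvent-cubic classification is evaluated as a consistency cross-check
    on root existence only.
    """
    roots = np.roots([1.0, m.M3, m.M2, m.M1, m.M0])
    zs = sorted(
        (
            r.real
            for r in roots
            if abs(r.imag) <= _REAL_ROOT_TOL * (1.0 + abs(r.real))
            and r.real > _POSITIVE_ROOT_TOL
        ),
        reverse=True,
    )
    crossings = [
        Crossing(omega=math.sqrt(z), z=z, f_prime=_f_derivative(m, z), delta=transversality(math.sqrt(z), m))
        for z in zs
    ]
    predicted = _lemma1_predicts_root(m)
    if predicted is not None and predicted != bool(crossings):
        warnings.warn(
            "resolvent-cubic classification disagrees with the quartic solver "
            f"on root existence (predicted {predicted}, found {len(crossings)})",
            RuntimeWarning,
            stacklevel=2,
        )
    return crossings


def transversality(omega_star: float, m: FCoefficients) -> int:
    """Sign of d(Re lambda)/d tau at a crossing: sign of F'(omega*^2).

    Crossings with |F'| below a degeneracy tolerance (repeated root of F)
    return 0 and are excluded from Hopf claims.
    """
    z = omega_star**2
    fp = _f_derivative(m, z)
    scale = max(1.0, 4.0 * abs(z) ** 3, 3.0 * abs(m.M3) * z**2, 2.0 * abs(m.M2) * abs(z), abs(m.M1))
    if abs(fp) < _DEGENERATE_FPRIME_TOL * scale:
        return 0
    return 1 if fp > 0 else -1


def char_residual(omega: float, tau: float, coef: CharCoefficients) -> float:
    """Normalized modulus of the characteristic function at (i omega, tau).

    The modulus is divided by the sum of the moduli of the individual terms,
    so a genuine root gives a value at round-off level regardless of scale.
    """
    lam = 1j * omega
    terms = [
        lam**4,
        coef.A3 * lam**3,
        coef.A2 * lam**2,
        coef.A1 * lam,
        complex(coef.A0),
        (coef.B2 * lam**2 + coef.B1 * lam + coef.B0) * np.exp(-lam * tau),
    ]
    scale = sum(abs(t) for t in terms)
    return abs(sum(terms)) / max(scale, 1e-300)


def critical_delays(
    omega: float, coef: CharCoefficients, j_max: int
) -> np.ndarray:
    """The delay ladder ``tau_0 < tau_1 < ...`` for one crossing frequency.

    From the real/imaginary split of the characteristic equation at
    ``lambda = i omega``, ``cos(omega tau)`` and ``sin(omega tau)`` are
    rational in omega; the ladder is the arccos branch selected by the sign
    of the sine, advanced by full turns ``2 pi j / omega``, ``j = 0..j_max``.
    Every rung is residual-checked on the characteristic equation.
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    a3, a2, a1, a0 = coef.A3, coef.A2, coef.A1, coef.A0
    b2, b1, b0 = coef.B2, coef.B1, coef.B0
    den = b1**2 * omega**2 + (b0 - b2 * omega**2) ** 2
    fc = (
        (omega**4 - a2 * omega**2 + a0) * (b2 * omega**2 - b0)
        + b1 * omega * (a3 * omega**3 - a1 * omega)
    ) / den
    fs = (
        b1 * omega * (-(omega**4) + a2 * omega**2 - a0)
        + (b0 - b2 * omega**2) * (-a3 * omega**3 + a1 * omega)
    ) / den
    if abs(fc) > 1.0 + 1e-9:
        raise ConsistencyError(
            f"|cos(omega tau)| = {abs(fc)} > 1: omega is not a crossing frequency"
        )
    fc = min(1.0, max(-1.0, fc))
    base = math.acos(fc) if fs >= 0 else 2.0 * math.pi - math.acos(fc)
    taus = (base + 2.0 * math.pi * np.arange(j_max + 1)) / omega
    for t in taus:
        res = char_residual(omega, t, coef)
        if res > _RESIDUAL_TOL:
            raise ConsistencyError(
                f"characteristic residual {res:.3e} at (i*{omega}, tau={t}) exceeds "
                f"{_RESIDUAL_TOL}"
            )
    return taus


# ---------------------------------------------------------------------------
# full pipeline


@dataclass(frozen=True)
class HopfSummary:
    """End-to-end delay-stability analysis at the positive equilibrium.

    ``regime`` is one of

    - ``"stable_for_all_tau"``: no imaginary-axis crossing exists and the
      tau=0 quartic is Hurwitz — E* is locally asymptotically stable for
      every delay;
    - ``"stable_below_tau_star"``: E* is stable on [0, tau*) and loses
      stability at the smallest critical delay ``tau_star`` (a Hopf point
      when ``delta != 0``).  Later rungs with alternating transversality
      signs mark further stability switches (restabilization windows are
      recoverable from the ladders);
    - ``"unstable_at_tau0"``: the Routh-Hurwitz conditions already fail at
      tau = 0; no Hopf claim is made.
    """

    equilibrium: EquilibriumState
    coefficients: CharCoefficients
    m: FCoefficients
    routh_hurwitz: RouthHurwitz
    crossings: tuple[Crossing, ...]
    tau_star: float | None
    omega_star: float | None
    delta: int | None
    regime: str

    @property
    def stable_tau0(self) -> bool:
        return self.routh_hurwitz.stable


def hopf_summary(params: ModelParameters, tau_max: float = 50.0) -> HopfSummary:
    """Run the full pipeline: E* -> coefficients -> crossings -> ladders.

    Requires ``R0 > 1`` (otherwise there is no positive equilibrium and a
    ``ValueError`` is raised).  ``tau_max`` bounds the delay ladders: each
    crossing's ladder is extended ``ceil(tau_max * omega / 2 pi) + 1`` rungs.
    """
    eq = find_positive_equilibrium(params)
    if eq is None:
        raise ValueError("R0 < 1: no positive equilibrium, nothing to analyze")
    coef = char_coefficients(eq, params)
    rh = routh_hurwitz_tau0(coef)
    m = f_poly(coef)
    bare = positive_crossings(m)
    crossings = []
    for cr in bare:
        j_max = math.ceil(tau_max * cr.omega / (2.0 * math.pi)) + 1
        delays = critical_delays(cr.omega, coef, j_max)
        crossings.append(
            Crossing(omega=cr.omega, z=cr.z, f_prime=cr.f_prime, delta=cr.delta, delays=delays)
        )

    if not rh.stable:
        regime = "unstable_at_tau0"
        tau_star = omega_star = delta = None
    elif not crossings:
        regime = "stable_for_all_tau"
        tau_star = omega_star = delta = None
    else:
        first = min(crossings, key=lambda c: c.delays[0])
        tau_star = float(first.delays[0])
        omega_star = first.omega
        delta = first.delta
        regime = "stable_below_tau_star"
    return HopfSummary(
        equilibrium=eq,
        coefficients=coef,
        m=m,
        routh_hurwitz=rh,
        crossings=tuple(crossings),
        tau_star=tau_star,
        omega_star=omega_star,
        delta=delta,
        regime=regime,
    )
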