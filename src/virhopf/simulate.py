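"""Fixed-step RK4 integration of the delayed model by the method of steps.

The delay enters only through ``w(t - tau)`` in the CTL equation.  The step
size is snapped to an integer fraction of the delay (``h = tau/m``), so both
``t - tau`` and ``t + h - tau`` land on stored grid nodes; the half-stage
lookup ``t + h/2 - tau`` falls mid-interval and is served by cubic Hermite
interpolation between the two bracketing nodes (values + stored derivatives),
preserving the classical fourth order of the stepper.  ``tau = 0`` reduces to
a plain ODE handled by the same loop.

Trajectories are checked against the theoretical nonnegativity and ultimate
boundedness of the model: components within a round-off band below zero are
clipped; larger negativity or blow-up beyond 1000x the ultimate bound aborts
the run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import ConfigurationError, DivergenceError, NegativityError
from .incidence import incidence_value, value_closure
from .model import ModelParameters

__all__ = ["HistoryFunction", "Trajectory", "rhs", "integrate", "default_history"]

#: negativity clipping band, as a fraction of each component's ultimate bound
_NEG_BAND = 1e-9
#: divergence guard, as a multiple of each component's ultimate bound
_DIVERGENCE_FACTOR = 1e3


def rhs(
    state: Sequence[float], delayed_w: float, params: ModelParameters
) -> tuple[float, float, float, float]:
    """Right-hand side of the model at *state* with lagged ``w(t-tau)``.

    Note that the incidence terms cancel in ``d(u+w)/dt``, which equals
    ``s - d1*u - d2*w - p*w*z`` exactly; this is what bounds the cell
    populations.
    """
    u, w, v, z = state
    f1 = incidence_value(params.f1, u, v)
    f2 = incidence_value(params.f2, u, w)
    inc = f1 * v + f2 * w
    return (
        params.s - inc - params.d1 * u,
        inc - params.d2 * w - params.p * w * z,
        params.k * w - params.d3 * v,
        params.c * delayed_w - params.d4 * z,
    )


@dataclass(frozen=True)
class HistoryFunction:
    """Initial history ``phi(theta)`` for ``theta in [-tau, 0]``.

    Either a constant nonnegative 4-vector or an arbitrary callable mapping
    ``theta`` to a nonnegative 4-vector.
    """

    kind: str  # "constant" | "callable"
    value: tuple[float, float, float, float] | None = None
    fn: Callable[[float], Sequence[float]] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.kind == "constant":
            if self.value is None or len(self.value) != 4:
                raise ConfigurationError("constant history needs a 4-vector value")
            if any(x < 0 for x in self.value):
                raise ConfigurationError("history must be nonnegative")
        elif self.kind == "callable":
            if self.fn is None:
                raise ConfigurationError("callable history needs fn")
        else:
            raise ConfigurationError(f"unknown history kind {self.kind!r}")

    @classmethod
    def constant(cls, state: Sequence[float]) -> "HistoryFunction":
        return cls("constant", value=tuple(float(x) for x in state))

    @classmethod
    def from_callable(cls, fn: Callable[[float], Sequence[float]]) -> "HistoryFunction":
        return cls("callable", fn=fn)

    def __call__(self, theta: float) -> tuple[float, float, float, float]:
        if self.kind == "constant":
            return self.value
        out = tuple(float(x) for x in self.fn(theta))
        if len(out) != 4:
            raise ConfigurationError("history callable must return a 4-vector")
        if any(x < 0 for x in out):
            raise ConfigurationError(f"history must be nonnegative, got {out} at {theta}")
        return out


def default_history(params: ModelParameters) -> HistoryFunction:
    """Reference constant history.

    95% of the positive equilibrium when it exists (a small perturbation that
    reaches the local attractor quickly), otherwise ``(0.9*u0, 1, 1, 1)``.
    """
    from .equilibria import find_positive_equilibrium

    try:
        eq = find_positive_equilibrium(params)
    except Exception:
        eq = None
    if eq is not None:
        return HistoryFunction.constant((0.95 * eq.u, 0.95 * eq.w, 0.95 * eq.v, 0.95 * eq.z))
    return HistoryFunction.constant((0.9 * params.u0, 1.0, 1.0, 1.0))


@dataclass
class Trajectory:
    """Equally spaced solution samples with dense lookup for ``w``.

    ``states`` has shape ``(n+1, 4)`` with columns ``u, w, v, z``;
    ``times[i] = i*step``.  ``w_derivatives`` stores dw/dt at the nodes and
    backs the cubic Hermite evaluation of ``w`` between nodes.
    """

    times: np.ndarray
    states: np.ndarray
    step: float
    tau: float
    w_derivatives: np.ndarray
    history: HistoryFunction | None = None

    @property
    def u(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def w(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def v(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def z(self) -> np.ndarray:
        return self.states[:, 3]

    @property
    def t_end(self) -> float:
        return float(self.times[-1])

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def w_at(self, t: float) -> float:
        """Dense evaluation of ``w(t)``, including the history for ``t < 0``."""
        if t < 0.0:
            if self.history is None:
                raise ValueError("no history attached; t must be >= 0")
            if t < -self.tau - 1e-12:
                raise ValueError(f"t={t} precedes the history interval")
            return self.history(max(t, -self.tau))[1]
        if t > self.t_end + 1e-12:
            raise ValueError(f"t={t} beyond the integrated horizon {self.t_end}")
        h = self.step
        x = t / h
        i = min(int(x), len(self.times) - 2)
        theta = x - i
        w0, w1 = self.states[i, 1], self.states[i + 1, 1]
        dw0, dw1 = self.w_derivatives[i], self.w_derivatives[i + 1]
        t2 = theta * theta
        t3 = t2 * theta
        return (
            (2 * t3 - 3 * t2 + 1) * w0
            + (t3 - 2 * t2 + theta) * h * dw0
            + (-2 * t3 + 3 * t2) * w1
            + (t3 - t2) * h * dw1
        )


def _ultimate_bounds(params: ModelParameters) -> tuple[float, float, float, float]:
    d = min(params.d1, params.d2)
    n_bound = params.s / d
    return (n_bound, n_bound, params.k * n_bound / params.d3, params.c * n_bound / params.d4)


def integrate(
    params: ModelParameters,
    history: HistoryFunction | None = None,
    t_end: float = 1000.0,
    step: float = 0.01,
    check_bounds: bool = True,
) -> Trajectory:
    """Integrate the model from its initial history.

    Parameters
    ----------
    params
        Model parameters including the delay.
    history
        Initial history on ``[-tau, 0]``; defaults to :func:`default_history`.
    t_end
        Requested horizon; rounded up to a whole number of steps.
    step
        Requested step size.  For ``tau > 0`` the actual step is
        ``tau / round(tau/step)`` so that the lag is a whole number of steps.
    check_bounds
        Abort with :class:`DivergenceError` if a component exceeds 1000x its
        theoretical ultimate bound (signals a solver or parameter problem).

    Returns
    -------
    Trajectory
    """
    if t_end <= 0:
        raise ConfigurationError("t_end must be > 0")
    if step <= 0:
        raise ConfigurationError("step must be > 0")
    if history is None:
        history = default_history(params)

    tau = params.tau
    if tau > 0:
        m = max(1, round(tau / step))
        h = tau / m
    else:
        m = 0
        h = step
    n = math.ceil(t_end / h - 1e-9)

    s, d1, d2, d3, d4 = params.s, params.d1, params.d2, params.d3, params.d4
    p, k, c = params.p, params.k, params.c
    f1 = value_closure(params.f1)
    f2 = value_closure(params.f2)

    bounds = _ultimate_bounds(params)
    neg_band = tuple(_NEG_BAND * b for b in bounds)
    init = history(0.0)
    # the history itself may start above the *ultimate* bounds
    div_limit = tuple(
        _DIVERGENCE_FACTOR * max(b, abs(x)) for b, x in zip(bounds, init)
    )

    u, w, v, z = init
    us = [u]
    ws = [w]
    vs = [v]
    zs = [z]
    wdots: list[float] = []

    def hist_w(t: float) -> float:
        return history(max(t, -tau))[1]

    half = 0.5 * h
    sixth = h / 6.0
    for i in range(n):
        t = i * h
        # --- delayed w at the three stage times -------------------------
        if m == 0:
            wl0 = wlm = wl1 = None  # ODE: lag equals the current stage value
        else:
            j = i - m
            wl0 = ws[j] if j >= 0 else hist_w(t - tau)
            wl1 = ws[j + 1] if j + 1 >= 0 else hist_w(t + h - tau)

        # k1 (also the stored node derivative of w)
        fv1 = f1(u, v)
        fw1 = f2(u, w)
        inc = fv1 * v + fw1 * w
        k1u = s - inc - d1 * u
        k1w = inc - d2 * w - p * w * z
        k1v = k * w - d3 * v
        k1z = c * (w if m == 0 else wl0) - d4 * z
        wdots.append(k1w)

        if m != 0:
            if i + 0.5 - m <= 0:
                wlm = hist_w(t + half - tau)
            else:
                # cubic Hermite at the interval midpoint
                wlm = 0.5 * (ws[j] + ws[j + 1]) + 0.125 * h * (wdots[j] - wdots[j + 1])

        # k2
        u2 = u + half * k1u
        w2 = w + half * k1w
        v2 = v + half * k1v
        z2 = z + half * k1z
        fv = f1(u2, v2)
        fw = f2(u2, w2)
        inc = fv * v2 + fw * w2
        k2u = s - inc - d1 * u2
        k2w = inc - d2 * w2 - p * w2 * z2
        k2v = k * w2 - d3 * v2
        k2z = c * (w2 if m == 0 else wlm) - d4 * z2

        # k3
        u3 = u + half * k2u
        w3 = w + half * k2w
        v3 = v + half * k2v
        z3 = z + half * k2z
        fv = f1(u3, v3)
        fw = f2(u3, w3)
        inc = fv * v3 + fw * w3
        k3u = s - inc - d1 * u3
        k3w = inc - d2 * w3 - p * w3 * z3
        k3v = k * w3 - d3 * v3
        k3z = c * (w3 if m == 0 else wlm) - d4 * z3

        # k4
        u4 = u + h * k3u
        w4 = w + h * k3w
        v4 = v + h * k3v
        z4 = z + h * k3z
        fv = f1(u4, v4)
        fw = f2(u4, w4)
        inc = fv * v4 + fw * w4
        k4u = s - inc - d1 * u4
        k4w = inc - d2 * w4 - p * w4 * z4
        k4v = k * w4 - d3 * v4
        k4z = c * (w4 if m == 0 else wl1) - d4 * z4

        u = u + sixth * (k1u + 2.0 * (k2u + k3u) + k4u)
        w = w + sixth * (k1w + 2.0 * (k2w + k3w) + k4w)
        v = v + sixth * (k1v + 2.0 * (k2v + k3v) + k4v)
        z = z + sixth * (k1z + 2.0 * (k2z + k3z) + k4z)

        if u < 0.0 or w < 0.0 or v < 0.0 or z < 0.0:
            state = [u, w, v, z]
            for idx in range(4):
                if state[idx] < 0.0:
                    if state[idx] >= -neg_band[idx]:
                        state[idx] = 0.0
                    else:
                        raise NegativityError(
                            f"component {('u', 'w', 'v', 'z')[idx]} = {state[idx]:.3e} "
                            f"at t={t + h:.6g} exceeds the round-off band"
                        )
            u, w, v, z = state
        if check_bounds and (
            u > div_limit[0] or w > div_limit[1] or v > div_limit[2] or z > div_limit[3]
        ):
            raise DivergenceError(
                f"state ({u:.3e}, {w:.3e}, {v:.3e}, {z:.3e}) at t={t + h:.6g} "
                f"exceeds 1000x the ultimate bounds {bounds}"
            )
        us.append(u)
        ws.append(w)
        vs.append(v)
        zs.append(z)

    # derivative at the final node (for dense evaluation)
    j = n - m
    wl = (ws[j] if j >= 0 else hist_w(n * h - tau)) if m != 0 else w
    wdots.append(rhs((u, w, v, z), wl, params)[1])

    states = np.column_stack(
        [np.asarray(us), np.asarray(ws), np.asarray(vs), np.asarray(zs)]
    )
    return Trajectory(
        times=np.arange(n + 1) * h,
        states=states,
        step=h,
        tau=tau,
        w_derivatives=np.asarray(wdots),
        history=history,
    )
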