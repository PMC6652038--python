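"""Delay scans, post-transient extrema and period-multiplicity detection.

A bifurcation diagram is assembled by integrating the model once per delay
value, discarding a transient, and recording all strict local maxima and
minima of the free-virus series ``v(t)`` in the remaining window — the
classical "max/min per parameter value" diagram.  The number of distinct
maxima levels, found by single-linkage clustering, estimates the period
multiplicity: one level is a simple limit cycle, n repeating levels a
period-n solution, many non-repeating levels an (operationally) aperiodic
signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import IntegrationError
from .model import ModelParameters
from .simulate import HistoryFunction, Trajectory, default_history, integrate

__all__ = [
    "Extrema",
    "extrema_of_v",
    "period_multiplicity",
    "oscillation_sustained",
    "BifurcationPoint",
    "BifurcationDiagram",
    "scan_tau",
]

#: default single-linkage gap threshold, as a fraction of the maxima range
DEFAULT_CLUSTER_RTOL = 0.02
#: cluster counts beyond this are labelled aperiodic
MAX_PERIOD = 12
#: relative amplitude below which a window counts as settled at equilibrium
DEFAULT_EQUILIBRIUM_RTOL = 1e-3

MIN_MAXIMA_FOR_PERIOD = 6


@dataclass(frozen=True)
class Extrema:
    """Strict local extrema of ``v(t)`` on a window, in time order."""

    maxima: np.ndarray
    minima: np.ndarray
    maxima_times: np.ndarray
    minima_times: np.ndarray


def _runs(values: np.ndarray) -> list[tuple[float, int, int]]:
    """Compress consecutive equal values into (value, start, end) runs."""
    runs = []
    start = 0
    for i in range(1, len(values)):
        if values[i] != values[start]:
            runs.append((values[start], start, i - 1))
            start = i
    runs.append((values[start], start, len(values) - 1))
    return runs


def extrema_of_v(traj: Trajectory, transient: float) -> Extrema:
    """Local extrema of the virus series after discarding ``t <= transient``.

    Plateau runs (consecutive exactly-equal samples) collapse to a single
    extremum at their midpoint.  A window shorter than 10 samples is refused.
    """
    if transient >= traj.t_end:
        raise ValueError(f"transient {transient} must precede t_end {traj.t_end}")
    sel = traj.times > transient
    if sel.sum() < 10:
        raise ValueError("post-transient window holds fewer than 10 samples")
    v = traj.v[sel]
    t = traj.times[sel]

    max_v, min_v, max_t, min_t = [], [], [], []
    runs = _runs(v)
    for r in range(1, len(runs) - 1):
        val, start, end = runs[r]
        prev_val = runs[r - 1][0]
        next_val = runs[r + 1][0]
        mid = (start + end) // 2
        if prev_val < val and next_val < val:
            max_v.append(val)
            max_t.append(t[mid])
        elif prev_val > val and next_val > val:
            min_v.append(val)
            min_t.append(t[mid])
    return Extrema(
        maxima=np.asarray(max_v),
        minima=np.asarray(min_v),
        maxima_times=np.asarray(max_t),
        minima_times=np.asarray(min_t),
    )


def _cluster_labels(maxima: np.ndarray, rel_tol: float) -> np.ndarray:
    """Single-linkage clustering of 1-D values with a relative gap threshold.

    Returns a label per maximum (labels ordered by increasing cluster value).
    """
    order = np.argsort(maxima)
    sorted_vals = maxima[order]
    span = sorted_vals[-1] - sorted_vals[0]
    threshold = rel_tol * span
    labels_sorted = np.zeros(len(maxima), dtype=int)
    label = 0
    for i in range(1, len(sorted_vals)):
        if sorted_vals[i] - sorted_vals[i - 1] > threshold:
            label += 1
        labels_sorted[i] = label
    labels = np.empty(len(maxima), dtype=int)
    labels[order] = labels_sorted
    return labels


def period_multiplicity(
    maxima: np.ndarray, rel_tol: float = DEFAULT_CLUSTER_RTOL
) -> int | None:
    """Number of distinct repeating maxima levels, or ``None`` if aperiodic.

    Clusters the maxima by single-linkage with gap threshold
    ``rel_tol * (max - min)`` and checks that the time-ordered sequence of
    cluster labels repeats with period equal to the cluster count.  Returns
    0 for an empty list (equilibrium), 1 for a simple limit cycle, n for a
    period-n solution; ``None`` when the clusters do not repeat cyclically
    or exceed :data:`MAX_PERIOD` (an operational chaos label, not a proof).

    At least :data:`MIN_MAXIMA_FOR_PERIOD` maxima are required.
    """
    maxima = np.asarray(maxima, dtype=float)
    if maxima.size == 0:
        return 0
    if maxima.size < MIN_MAXIMA_FOR_PERIOD:
        raise ValueError(
            f"need >= {MIN_MAXIMA_FOR_PERIOD} maxima to assess periodicity, got {maxima.size}"
        )
    span = maxima.max() - maxima.min()
    if span <= 1e-12 * max(1.0, abs(maxima).max()):
        return 1  # all maxima at one level: simple limit cycle
    labels = _cluster_labels(maxima, rel_tol)
    n = int(labels.max()) + 1
    if n > MAX_PERIOD:
        return None
    if np.any(labels[n:] != labels[:-n]):
        return None
    return n


def oscillation_sustained(traj: Trajectory, fraction: float = 0.2, decay_ratio: float = 0.75) -> bool:
    """Whether the v-oscillation does not decay over the final *fraction* of the run.

    Compares the peak-to-peak amplitude of the last half of the window with
    the half before it; ``True`` when the amplitude has not dropped below
    ``decay_ratio`` times the earlier one.
    """
    v = traj.v
    n = len(v)
    i0 = int((1.0 - fraction) * n)
    mid = (i0 + n) // 2
    amp_a = v[i0:mid].max() - v[i0:mid].min()
    amp_b = v[mid:].max() - v[mid:].min()
    return amp_b >= decay_ratio * amp_a


# ---------------------------------------------------------------------------
# tau scans


@dataclass(frozen=True)
class BifurcationPoint:
    """One row of a diagram: all post-transient extrema at one delay."""

    tau: float
    maxima: np.ndarray
    minima: np.ndarray
    classification: str  # equilibrium | period-n | aperiodic | unresolved | diverged
    multiplicity: int | None
    final_state: np.ndarray | None


@dataclass(frozen=True)
class BifurcationDiagram:
    """Per-delay extrema of v(t) and attractor classification."""

    points: tuple[BifurcationPoint, ...]

    @property
    def tau_values(self) -> np.ndarray:
        return np.array([pt.tau for pt in self.points])

    def classification_of(self, tau: float) -> str:
        for pt in self.points:
            if pt.tau == tau:
                return pt.classification
        raise KeyError(tau)

    def onset_of_oscillation(self) -> float | None:
        """Smallest scanned delay that is no longer classified equilibrium."""
        for pt in self.points:
            if pt.classification not in ("equilibrium", "diverged"):
                return pt.tau
        return None

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (tau, extremum_type, value) for plotting/CSV."""
        rows = []
        for pt in self.points:
            for val in pt.maxima:
                rows.append((pt.tau, "max", val))
            for val in pt.minima:
                rows.append((pt.tau, "min", val))
            if pt.maxima.size == 0 and pt.classification == "equilibrium":
                rows.append((pt.tau, "equilibrium", pt.final_state[2]))
        return pd.DataFrame(rows, columns=["tau", "extremum_type", "value"])


def _classify(
    traj: Trajectory,
    transient: float,
    eq_rtol: float,
    eq_atol: float,
    cluster_rtol: float,
) -> tuple[str, int | None, Extrema]:
    ext = extrema_of_v(traj, transient)
    sel = traj.times > transient
    window = traj.v[sel]
    amplitude = window.max() - window.min()
    level = abs(window.mean())
    if amplitude < eq_atol + eq_rtol * level:
        return "equilibrium", 0, ext
    if ext.maxima.size < MIN_MAXIMA_FOR_PERIOD:
        return "unresolved", None, ext
    mult = period_multiplicity(ext.maxima, cluster_rtol)
    if mult is None:
        return "aperiodic", None, ext
    return f"period-{mult}", mult, ext


def scan_tau(
    params: ModelParameters,
    tau_grid,
    t_end: float = 5500.0,
    transient: float = 5000.0,
    step: float = 0.01,
    history: HistoryFunction | None = None,
    eq_rtol: float = DEFAULT_EQUILIBRIUM_RTOL,
    eq_atol: float = 1e-8,
    cluster_rtol: float = DEFAULT_CLUSTER_RTOL,
) -> BifurcationDiagram:
    """One integration per delay on *tau_grid*; extrema plus classification.

    Each delay starts from the same fresh history (the default near-E*
    history unless one is supplied) — no continuation between rows, so
    coexisting attractors appear as whichever basin the history falls in.
    A divergent integration flags its row and the scan continues.
    """
    if t_end <= transient:
        raise ValueError("t_end must exceed transient")
    if history is None:
        history = default_history(params)
    points = []
    for tau in tau_grid:
        pars = params.with_tau(float(tau))
        try:
            traj = integrate(pars, history=history, t_end=t_end, step=step)
        except IntegrationError:
            points.append(
                BifurcationPoint(
                    tau=float(tau),
                    maxima=np.array([]),
                    minima=np.array([]),
                    classification="diverged",
                    multiplicity=None,
                    final_state=None,
                )
            )
            continue
        label, mult, ext = _classify(traj, transient, eq_rtol, eq_atol, cluster_rtol)
        points.append(
            BifurcationPoint(
                tau=float(tau),
                maxima=ext.maxima,
                minima=ext.minima,
                classification=label,
                multiplicity=mult,
                final_state=traj.final_state,
            )
        )
    return BifurcationDiagram(points=tuple(points))
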