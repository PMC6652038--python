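"""Structured report writers behind the command-line interface.

Every report is a JSON summary plus, where natural, a CSV payload, written
into an output directory together with a metadata record (full parameter
set, solver settings, library versions) sufficient to re-run the command
bit-identically.  Logging goes to stderr and never mixes with the
machine-readable outputs.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .bifurcation import scan_tau
from .equilibria import basic_reproduction_number, find_positive_equilibrium, infection_free_equilibrium
from .scenarios import Scenario, scenario_to_dict
from .simulate import integrate
from .stability import hopf_summary

__all__ = ["run_report"]

log = logging.getLogger("virhopf")


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _metadata(scenario: Scenario, settings: dict) -> dict:
    return {
        "scenario": scenario_to_dict(scenario),
        "settings": _jsonable(settings),
        "versions": {
            "virhopf": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "python": platform.python_version(),
        },
    }


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(_jsonable(payload), indent=2) + "\n")


def _analyze(scenario: Scenario, out: Path, settings: dict) -> dict:
    params = scenario.params
    r0 = basic_reproduction_number(params)
    e0 = infection_free_equilibrium(params)
    star = find_positive_equilibrium(params)
    payload = {
        "R0": {"value": r0.r0, "virus_to_cell": r0.virus_to_cell, "cell_to_cell": r0.cell_to_cell},
        "infection_free": {"u": e0.u, "w": e0.w, "v": e0.v, "z": e0.z},
        "positive": None
        if star is None
        else {
            "u": star.u,
            "w": star.w,
            "v": star.v,
            "z": star.z,
            "max_residual": star.max_residual,
        },
    }
    _write_json(out / "analyze.json", payload)
    rows = [("infection_free", e0.u, e0.w, e0.v, e0.z)]
    if star is not None:
        rows.append(("positive", star.u, star.w, star.v, star.z))
    pd.DataFrame(rows, columns=["kind", "u", "w", "v", "z"]).to_csv(
        out / "equilibria.csv", index=False
    )
    return payload


def _hopf(scenario: Scenario, out: Path, settings: dict) -> dict:
    summary = hopf_summary(scenario.params, tau_max=settings.get("tau_max", 50.0))
    coef = summary.coefficients
    payload = {
        "regime": summary.regime,
        "tau_star": summary.tau_star,
        "omega_star": summary.omega_star,
        "delta": summary.delta,
        "routh_hurwitz": {
            "H1": summary.routh_hurwitz.H1,
            "H2": summary.routh_hurwitz.H2,
            "stable_tau0": summary.routh_hurwitz.stable,
        },
        "coefficients": {
            name: getattr(coef, name)
            for name in ("A3", "A2", "A1", "A0", "B2", "B1", "B0", "Q0", "Q1", "Q2")
        },
        "F": dict(zip(("M3", "M2", "M1", "M0"), summary.m)),
        "crossings": [
            {"omega": c.omega, "delta": c.delta, "delays": c.delays}
            for c in summary.crossings
        ],
    }
    _write_json(out / "hopf.json", payload)
    rows = [
        (c.omega, c.delta, j, tau)
        for c in summary.crossings
        for j, tau in enumerate(c.delays)
    ]
    pd.DataFrame(rows, columns=["omega", "delta", "j", "tau"]).to_csv(
        out / "delay_ladder.csv", index=False
    )
    return payload


def _simulate(scenario: Scenario, out: Path, settings: dict) -> dict:
    params = scenario.params
    if settings.get("tau") is not None:
        params = params.with_tau(settings["tau"])
    traj = integrate(
        params,
        t_end=settings.get("t_end", 1000.0),
        step=settings.get("step", 0.01),
    )
    stride = max(1, int(settings.get("stride", 1)))
    frame = pd.DataFrame(
        {
            "t": traj.times[::stride],
            "u": traj.u[::stride],
            "w": traj.w[::stride],
            "v": traj.v[::stride],
            "z": traj.z[::stride],
        }
    )
    frame.to_csv(out / "trajectory.csv", index=False)
    payload = {
        "tau": params.tau,
        "t_end": traj.t_end,
        "step": traj.step,
        "final_state": dict(zip("uwvz", traj.final_state)),
    }
    _write_json(out / "simulate.json", payload)
    return payload


def _scan(scenario: Scenario, out: Path, settings: dict) -> dict:
    sc = scenario.scan
    grid = settings.get("tau_grid")
    if grid is None:
        grid = np.arange(sc.tau_min, sc.tau_max + 0.5 * sc.tau_step, sc.tau_step)
    diagram = scan_tau(
        scenario.params,
        grid,
        t_end=settings.get("t_end", sc.t_end),
        transient=settings.get("transient", sc.transient),
        step=settings.get("step", sc.step),
    )
    diagram.to_frame().to_csv(out / "scan.csv", index=False)
    payload = {
        "classification": {
            str(pt.tau): pt.classification for pt in diagram.points
        },
        "onset_of_oscillation": diagram.onset_of_oscillation(),
    }
    _write_json(out / "scan.json", payload)
    if settings.get("plot"):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 4))
        for pt in diagram.points:
            for val in pt.maxima:
                ax.plot(pt.tau, val, "k.", ms=2)
            for val in pt.minima:
                ax.plot(pt.tau, val, "b.", ms=2)
            if pt.classification == "equilibrium" and pt.final_state is not None:
                ax.plot(pt.tau, pt.final_state[2], "r.", ms=2)
        ax.set_xlabel(r"delay $\tau$")
        ax.set_ylabel("extrema of v(t)")
        ax.set_title(scenario.name)
        fig.tight_layout()
        fig.savefig(out / "scan.png", dpi=150)
        plt.close(fig)
    return payload


_COMMANDS = {"analyze": _analyze, "hopf": _hopf, "simulate": _simulate, "scan": _scan}


def run_report(scenario: Scenario, command: str, out_dir: str | Path, **settings) -> dict:
    """Run *command* for *scenario* and write its report files into *out_dir*.

    Returns the JSON-ready summary payload.
    """
    if command not in _COMMANDS:
        raise ValueError(f"unknown command {command!r}; expected one of {sorted(_COMMANDS)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("running %s for scenario %s -> %s", command, scenario.name, out)
    payload = _COMMANDS[command](scenario, out, settings)
    _write_json(out / f"{command}_metadata.json", _metadata(scenario, settings))
    return payload
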