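"""Built-in study scenarios and the YAML/JSON scenario config format.

All built-in fixtures share the virion/CTL constants ``d3=2.4, d4=1.618,
p=0.812, k=200`` and differ in recruitment, death rates and incidence
family; together they exercise the four incidence families:

==========  =====================  =============================================
name        incidence              highlight
==========  =====================  =============================================
case1a      bilinear (s=2)         Hopf bifurcation, low recruitment
case1b      bilinear (s=10)        stability windows: stable at tau=15, periodic
                                   at tau=20
case2a      saturation (s=10)      clean single Hopf point
case2b      saturation (s=20)      period-three window in the scan
case3a      Beddington-DeAngelis   chaotic window around tau=22
case3b      Beddington-DeAngelis   second interference setting
case4a      Hattaf-Yousfi          Hopf only, no chaos on [0, 50]
case4b      Hattaf-Yousfi          period-three window
==========  =====================  =============================================
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .incidence import IncidenceSpec
from .model import ModelParameters

__all__ = [
    "ScanSettings",
    "Scenario",
    "builtin_scenarios",
    "get_scenario",
    "scenario_to_dict",
    "scenario_from_dict",
    "save_scenario",
    "load_scenario",
]

#: constants shared by every built-in fixture
SHARED = dict(d3=2.4, d4=1.618, p=0.812, k=200.0)


@dataclass(frozen=True)
class ScanSettings:
    """Defaults for a delay scan of this scenario."""

    tau_min: float = 0.0
    tau_max: float = 50.0
    tau_step: float = 0.5
    t_end: float = 5500.0
    transient: float = 5000.0
    step: float = 0.01


@dataclass(frozen=True)
class Scenario:
    """A named parameter set with delays of interest and scan settings."""

    name: str
    params: ModelParameters
    taus_of_interest: tuple[float, ...] = ()
    scan: ScanSettings = field(default_factory=ScanSettings)
    notes: str = ""


def _params(s, c, d1, d2, f1, f2, tau=0.0) -> ModelParameters:
    return ModelParameters(s=s, c=c, d1=d1, d2=d2, tau=tau, f1=f1, f2=f2, **SHARED)


def builtin_scenarios() -> list[Scenario]:
    """The eight built-in study fixtures."""
    bilinear = dict(c=0.05, d1=0.01, d2=0.4)
    sat = dict(c=1.0, d1=0.01, d2=0.03)
    return [
        Scenario(
            "case1a",
            _params(
                s=2.0,
                f1=IncidenceSpec.bilinear(0.00025),
                f2=IncidenceSpec.bilinear(0.00065),
                **bilinear,
            ),
            taus_of_interest=(15.0, 20.0),
            notes="bilinear incidence, low recruitment",
        ),
        Scenario(
            "case1b",
            _params(
                s=10.0,
                f1=IncidenceSpec.bilinear(0.00025),
                f2=IncidenceSpec.bilinear(0.00065),
                **bilinear,
            ),
            taus_of_interest=(15.0, 20.0),
            notes="bilinear incidence; stable at tau=15, periodic at tau=20",
        ),
        Scenario(
            "case2a",
            _params(
                s=10.0,
                f1=IncidenceSpec.saturation(0.002, 1.0),
                f2=IncidenceSpec.saturation(0.003, 1.0),
                **sat,
            ),
            taus_of_interest=(4.0, 6.0),
            notes="saturation incidence; single Hopf point near tau ~ 4.9",
        ),
        Scenario(
            "case2b",
            _params(
                s=20.0,
                f1=IncidenceSpec.saturation(0.02, 0.1),
                f2=IncidenceSpec.saturation(0.03, 0.4),
                **sat,
            ),
            taus_of_interest=(35.0, 45.0),
            notes="saturation incidence; period-three window in the scan",
        ),
        Scenario(
            "case3a",
            _params(
                s=20.0,
                c=1.0,
                d1=0.1,
                d2=0.3,
                f1=IncidenceSpec.beddington_deangelis(0.02, 0.08, 0.5),
                f2=IncidenceSpec.beddington_deangelis(0.03, 0.08, 0.5),
            ),
            taus_of_interest=(10.0, 22.0, 45.0),
            notes="Beddington-DeAngelis; chaotic window around tau=22",
        ),
        Scenario(
            "case3b",
            _params(
                s=20.0,
                c=1.0,
                d1=0.1,
                d2=0.3,
                f1=IncidenceSpec.beddington_deangelis(0.02, 0.01, 0.2),
                f2=IncidenceSpec.beddington_deangelis(0.03, 0.01, 0.2),
            ),
            taus_of_interest=(10.0, 22.0, 45.0),
            notes="Beddington-DeAngelis, weaker interference",
        ),
        Scenario(
            "case4a",
            _params(
                s=15.0,
                c=1.0,
                d1=0.01,
                d2=0.03,
                f1=IncidenceSpec.hattaf_yousfi(0.5, 1.0, 1.0, 1.0),
                f2=IncidenceSpec.hattaf_yousfi(0.3, 1.0, 1.0, 1.0),
            ),
            notes="Hattaf-Yousfi; Hopf bifurcation only, no chaos on [0, 50]",
        ),
        Scenario(
            "case4b",
            _params(
                s=20.0,
                c=1.0,
                d1=0.1,
                d2=0.3,
                f1=IncidenceSpec.hattaf_yousfi(0.02, 0.01, 0.3, 0.001),
                f2=IncidenceSpec.hattaf_yousfi(0.03, 0.01, 0.3, 0.001),
            ),
            taus_of_interest=(49.0,),
            notes="Hattaf-Yousfi; period-three window",
        ),
    ]


def get_scenario(name: str) -> Scenario:
    for sc in builtin_scenarios():
        if sc.name == name:
            return sc
    raise ConfigurationError(
        f"unknown scenario {name!r}; built-ins: {[s.name for s in builtin_scenarios()]}"
    )


# ---------------------------------------------------------------------------
# config round-trip


def scenario_to_dict(scenario: Scenario) -> dict:
    p = scenario.params
    return {
        "name": scenario.name,
        "notes": scenario.notes,
        "parameters": {
            "s": p.s,
            "d1": p.d1,
            "d2": p.d2,
            "d3": p.d3,
            "d4": p.d4,
            "p": p.p,
            "k": p.k,
            "c": p.c,
            "tau": p.tau,
            "f1": p.f1.to_dict(),
            "f2": p.f2.to_dict(),
        },
        "taus_of_interest": list(scenario.taus_of_interest),
        "scan": dataclasses.asdict(scenario.scan),
    }


def scenario_from_dict(data: dict) -> Scenario:
    try:
        raw = dict(data["parameters"])
        f1 = IncidenceSpec.from_dict(raw.pop("f1"))
        f2 = IncidenceSpec.from_dict(raw.pop("f2"))
        params = ModelParameters(f1=f1, f2=f2, **raw)
        return Scenario(
            name=data["name"],
            params=params,
            taus_of_interest=tuple(data.get("taus_of_interest", ())),
            scan=ScanSettings(**data.get("scan", {})),
            notes=data.get("notes", ""),
        )
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"malformed scenario config: {exc}") from exc


def save_scenario(scenario: Scenario, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(scenario_to_dict(scenario), sort_keys=False))


def load_scenario(path: str | Path) -> Scenario:
    data = yaml.safe_load(Path(path).read_text())
    return scenario_from_dict(data)
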