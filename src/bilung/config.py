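"""Scenario container and structured-text (YAML) configuration I/O.

A scenario bundles everything one simulation needs: ventilator settings,
the two lung parameter blocks, gas properties, and integration controls.
All configuration values are in clinical units (cmH2O gauge, mm, mL/cmH2O,
L, breaths/min, s); conversion to SI happens inside the library.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .engine import SimulationConfig, Trajectory, simulate
from .gas import GasProperties, ThrottleGeometry
from .lung import LungParameters
from .ventilator import VentilatorSettings

__all__ = [
    "Scenario",
    "reference_scenario",
    "scenario_from_dict",
    "scenario_to_dict",
    "load_scenario",
    "save_scenario",
]


@dataclass(frozen=True)
class Scenario:
    """Complete description of one simulation run."""

    settings: VentilatorSettings = field(default_factory=VentilatorSettings)
    lung_r: LungParameters = field(default_factory=LungParameters)
    lung_l: LungParameters = field(default_factory=LungParameters)
    gas: GasProperties = field(default_factory=GasProperties)
    sim: SimulationConfig = field(default_factory=SimulationConfig)

    def run(self) -> Trajectory:
        return simulate(self.settings, self.lung_r, self.lung_l, self.gas, self.sim)


def reference_scenario(**sim_overrides) -> Scenario:
    """The symmetric reference bench: both lungs C = 10 mL/cmH2O,
    d = 3.2 mm; ventilator IPAP 22 / EPAP 4 cmH2O, BPM 20, Ti 1 s,
    Tr 0.3 s; air at 293.15 K."""
    scenario = Scenario()
    if sim_overrides:
        scenario = replace(scenario, sim=replace(scenario.sim, **sim_overrides))
    return scenario


def _lung_from_dict(block: dict) -> LungParameters:
    throttle = ThrottleGeometry(
        d=block.get("d", 3.2), Cd=block.get("Cd", 1.0)
    )
    return LungParameters(
        C=block.get("C", 10.0), throttle=throttle, V0=block.get("V0", 1.5)
    )


def scenario_from_dict(cfg: dict) -> Scenario:
    """Build a scenario from a nested dict (e.g. parsed YAML).

    Recognised blocks: ``ventilator`` (IPAP, EPAP, BPM, Ti, Tr), ``lung_r``
    / ``lung_l`` (C, d, Cd, V0), ``gas`` (R_specific, k, theta), ``sim``
    (any :class:`SimulationConfig` field).  Missing blocks and keys fall
    back to the reference defaults.
    """
    known = {"ventilator", "lung_r", "lung_l", "gas", "sim"}
    unknown = set(cfg) - known
    if unknown:
        raise ValueError(f"unknown configuration blocks: {sorted(unknown)}")
    return Scenario(
        settings=VentilatorSettings(**cfg.get("ventilator", {})),
        lung_r=_lung_from_dict(cfg.get("lung_r", {})),
        lung_l=_lung_from_dict(cfg.get("lung_l", {})),
        gas=GasProperties(**cfg.get("gas", {})),
        sim=SimulationConfig(**cfg.get("sim", {})),
    )


def scenario_to_dict(scenario: Scenario) -> dict:
    """Inverse of :func:`scenario_from_dict` (clinical units)."""
    s, g, c = scenario.settings, scenario.gas, scenario.sim
    return {
        "ventilator": {
            "IPAP": s.IPAP, "EPAP": s.EPAP, "BPM": s.BPM, "Ti": s.Ti, "Tr": s.Tr
        },
        "lung_r": {
            "C": scenario.lung_r.C,
            "d": scenario.lung_r.throttle.d,
            "Cd": scenario.lung_r.throttle.Cd,
            "V0": scenario.lung_r.V0,
        },
        "lung_l": {
            "C": scenario.lung_l.C,
            "d": scenario.lung_l.throttle.d,
            "Cd": scenario.lung_l.throttle.Cd,
            "V0": scenario.lung_l.V0,
        },
        "gas": {"R_specific": g.R_specific, "k": g.k, "theta": g.theta},
        "sim": {
            "n_warmup_cycles": c.n_warmup_cycles,
            "n_record_cycles": c.n_record_cycles,
            "rel_tol": c.rel_tol,
            "abs_tol": c.abs_tol,
            "max_step": c.max_step,
            "output_dt": c.output_dt,
            "steady_tol": c.steady_tol,
        },
    }


def load_scenario(path) -> Scenario:
    """Load a scenario from a YAML file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return scenario_from_dict(cfg)


def save_scenario(scenario: Scenario, path) -> None:
    Path(path).write_text(yaml.safe_dump(scenario_to_dict(scenario), sort_keys=False))
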