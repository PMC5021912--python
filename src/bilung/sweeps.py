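"""One-at-a-time parameter sweeps against the fixed reference lung.

Each sweep perturbs a single knob — a right-lung parameter (compliance
``C_r`` or throttle diameter ``d_r``) or a ventilator control (IPAP, EPAP,
BPM, Ti, Tr) — while the left lung stays at the reference values
(C = 10 mL/cmH2O, d = 3.2 mm).  :func:`paper_reference_suite` returns the
full manifest of study grids as data; :func:`run_sweep` executes one
sweep into a summary table plus per-scenario trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .config import Scenario, reference_scenario
from .engine import Trajectory
from .gas import ThrottleGeometry
from .metrics import sweep_summary

__all__ = [
    "SWEEPABLE_PARAMETERS",
    "SweepSpec",
    "SweepResult",
    "apply_parameter",
    "run_sweep",
    "paper_reference_suite",
    "FLOW_RATIO_GRIDS",
]

#: Knobs a sweep may perturb, with the units used in sweep values.
SWEEPABLE_PARAMETERS = {
    "C_r": "mL/cmH2O",
    "d_r": "mm",
    "IPAP": "cmH2O",
    "EPAP": "cmH2O",
    "BPM": "1/min",
    "Ti": "s",
    "Tr": "s",
}

#: Coarse grids used for the instantaneous flow-ratio studies of the two
#: lung-side parameters (the share studies use the finer grids in the
#: reference suite).
FLOW_RATIO_GRIDS = {
    "C_r": (8.0, 12.0, 14.0),
    "d_r": (2.0, 2.8, 4.0),
}


def apply_parameter(scenario: Scenario, parameter: str, value: float) -> Scenario:
    """Return a copy of ``scenario`` with one swept knob replaced.

    Validation of the resulting scenario (e.g. Ti exceeding the cycle
    period after a BPM change) happens in the domain dataclasses and
    raises immediately.
    """
    if parameter == "C_r":
        return replace(scenario, lung_r=replace(scenario.lung_r, C=value))
    if parameter == "d_r":
        throttle = ThrottleGeometry(d=value, Cd=scenario.lung_r.throttle.Cd)
        return replace(scenario, lung_r=replace(scenario.lung_r, throttle=throttle))
    if parameter in ("IPAP", "EPAP", "BPM", "Ti", "Tr"):
        return replace(
            scenario, settings=replace(scenario.settings, **{parameter: value})
        )
    raise ValueError(
        f"unknown sweep parameter {parameter!r}; expected one of "
        f"{sorted(SWEEPABLE_PARAMETERS)}"
    )


@dataclass(frozen=True)
class SweepSpec:
    """A one-dimensional sweep: which knob, which grid, from which base."""

    parameter: str
    values: tuple[float, ...]
    base: Scenario = field(default_factory=reference_scenario)

    def __post_init__(self) -> None:
        if self.parameter not in SWEEPABLE_PARAMETERS:
            raise ValueError(
                f"unknown sweep parameter {self.parameter!r}; expected one of "
                f"{sorted(SWEEPABLE_PARAMETERS)}"
            )
        if len(self.values) == 0:
            raise ValueError("sweep needs at least one value")
        if any(b <= a for a, b in zip(self.values, self.values[1:])):
            raise ValueError("sweep values must be strictly increasing")

    def scenarios(self) -> list[tuple[float, Scenario]]:
        """Materialise (and thereby validate) every perturbed scenario.

        Raises naming the offending value before any simulation runs.
        """
        out = []
        for v in self.values:
            try:
                out.append((v, apply_parameter(self.base, self.parameter, v)))
            except ValueError as err:
                raise ValueError(
                    f"sweep value {self.parameter}={v} is invalid: {err}"
                ) from err
        return out


@dataclass
class SweepResult:
    """Summary table plus the per-scenario trajectories of one sweep."""

    spec: SweepSpec
    table: pd.DataFrame
    trajectories: dict[float, Trajectory]


def run_sweep(spec: SweepSpec) -> SweepResult:
    """Simulate every scenario of the sweep and summarise.

    Scenarios are independent, so results do not depend on execution
    order; the table is sorted by swept value and re-running reproduces
    it bit-for-bit (the model has no stochastic element).
    """
    scenarios = spec.scenarios()  # validates all values up front
    results = []
    trajectories = {}
    for value, scenario in scenarios:
        traj = scenario.run()
        trajectories[value] = traj
        results.append((value, traj))
    table = sweep_summary(spec.parameter, results)
    return SweepResult(spec=spec, table=table, trajectories=trajectories)


def paper_reference_suite(base: Scenario | None = None) -> dict[str, SweepSpec]:
    """Manifest of the seven reference sweep families (no execution).

    Grids: right-lung compliance 5–30 mL/cmH2O every 5; right throttle
    diameter 1.6–4.0 mm every 0.4; IPAP {18, 22, 24} and EPAP {4, 6, 8}
    cmH2O; BPM {20, 25, 30}; Ti {1.0, 1.2, 1.4} s; Tr {0.2, 0.3, 0.4} s.
    The coarse flow-ratio grids for C_r and d_r are in
    :data:`FLOW_RATIO_GRIDS`.
    """
    base = base or reference_scenario()
    grids = {
        "C_r": (5.0, 10.0, 15.0, 20.0, 25.0, 30.0),
        "d_r": (1.6, 2.0, 2.4, 2.8, 3.2, 3.6, 4.0),
        "IPAP": (18.0, 22.0, 24.0),
        "EPAP": (4.0, 6.0, 8.0),
        "BPM": (20.0, 25.0, 30.0),
        "Ti": (1.0, 1.2, 1.4),
        "Tr": (0.2, 0.3, 0.4),
    }
    return {
        name: SweepSpec(parameter=name, values=values, base=base)
        for name, values in grids.items()
    }
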