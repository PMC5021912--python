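"""Shared fixtures: the reference bench scenario and cached trajectories.

Simulations are deterministic, so session-scoped trajectories are safe to
share between tests; they cut suite runtime substantially.
"""

from __future__ import annotations

import pytest
from hypothesis import settings

from bilung import (
    GasProperties,
    Scenario,
    apply_parameter,
    reference_scenario,
)

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def gas() -> GasProperties:
    return GasProperties()


@pytest.fixture(scope="session")
def ref_scenario() -> Scenario:
    return reference_scenario()


@pytest.fixture(scope="session")
def ref_traj(ref_scenario):
    """Symmetric reference bench: both lungs C=10 mL/cmH2O, d=3.2 mm;
    IPAP 22 / EPAP 4 cmH2O, BPM 20, Ti 1 s, Tr 0.3 s."""
    return ref_scenario.run()


@pytest.fixture(scope="session")
def asym_c_traj(ref_scenario):
    """Right lung stiffer than left: C_r = 8, C_l = 10 mL/cmH2O."""
    return apply_parameter(ref_scenario, "C_r", 8.0).run()
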