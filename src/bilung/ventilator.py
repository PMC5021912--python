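"""BIPAP ventilator setpoint waveform.

A bi-level positive airway pressure ventilator cycles between two pressure
levels: EPAP (the expiratory baseline) and IPAP (the inspiratory level).
Five scalars define each breath: IPAP, EPAP, the respiratory rate BPM, the
inspiratory time Ti, and the pressure rise time Tr.  The waveform used here
is the trapezoid conventional for pressure-targeted modes: a linear ramp
from EPAP to IPAP over ``[0, Tr)``, a plateau at IPAP over ``[Tr, Ti)``,
and a step release back to EPAP for the rest of the cycle.  The shape is
isolated behind :func:`pressure_setpoint` so a variant (e.g. exponential
rise) can be substituted without touching the integrator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["VentilatorSettings", "cycle_period", "pressure_setpoint"]


@dataclass(frozen=True)
class VentilatorSettings:
    """The five BIPAP controls.

    Attributes
    ----------
    IPAP, EPAP : float
        Inspiratory / expiratory positive airway pressure, cmH2O gauge.
        ``IPAP >= EPAP >= 0``.
    BPM : float
        Breaths per minute; the cycle period is ``60/BPM`` s.
    Ti : float
        Inspiratory time, s (high-pressure phase duration).
    Tr : float
        Pressure rise time, s; ``0 < Tr <= Ti < 60/BPM``.
    """

    IPAP: float = 22.0
    EPAP: float = 4.0
    BPM: float = 20.0
    Ti: float = 1.0
    Tr: float = 0.3

    def __post_init__(self) -> None:
        if not self.EPAP >= 0.0:
            raise ValueError(f"EPAP must be non-negative, got {self.EPAP}")
        if not self.IPAP >= self.EPAP:
            raise ValueError(
                f"IPAP ({self.IPAP}) must be at least EPAP ({self.EPAP})"
            )
        if not self.BPM > 0.0:
            raise ValueError(f"BPM must be positive, got {self.BPM}")
        period = 60.0 / self.BPM
        if not 0.0 < self.Tr <= self.Ti:
            raise ValueError(
                f"rise time Tr={self.Tr} must satisfy 0 < Tr <= Ti={self.Ti}"
            )
        if not self.Ti < period:
            raise ValueError(
                f"inspiratory time Ti={self.Ti} must fit inside the "
                f"cycle period {period:g} s (BPM={self.BPM})"
            )


def cycle_period(settings: VentilatorSettings) -> float:
    """Breath cycle period 60/BPM, s."""
    return 60.0 / settings.BPM


def pressure_setpoint(t, settings: VentilatorSettings):
    """Ventilator pressure setpoint at time ``t``, cmH2O gauge.

    ``t`` is measured from any cycle start and is extended periodically;
    scalars and arrays are accepted.  The ventilator is modelled as an
    ideal pressure source: it holds this setpoint regardless of flow.
    """
    T = cycle_period(settings)
    tau = np.asarray(t, dtype=float) % T
    ramp = settings.EPAP + (settings.IPAP - settings.EPAP) * tau / settings.Tr
    out = np.select(
        [tau < settings.Tr, tau < settings.Ti],
        [ramp, settings.IPAP],
        default=settings.EPAP,
    )
    if np.ndim(t) == 0:
        return float(out)
    return out
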