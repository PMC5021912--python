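"""Per-lung state and the isothermal pressure/volume/mass dynamics.

Each lung is a variable-volume container of ideal gas at the common
temperature theta, characterised by a linear respiratory compliance
``C = dV/dp`` and an equivalent inlet throttle.  Differentiating the gas
law ``p V = m R theta`` at constant temperature and eliminating ``dV``
with the compliance definition gives the pressure rate

    dp/dt = R theta q V / (V^2 + C m R theta)

with ``dV/dt = C dp/dt`` and ``dm/dt = q``, where ``q`` is the mass inflow
through the throttle.  The three states are integrated redundantly; the
gas law then serves as a free accuracy diagnostic (see
:func:`ideal_gas_residual`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .gas import CMH2O_TO_PA, GasProperties, ThrottleGeometry, cmh2o_to_pa_abs

__all__ = ["LungParameters", "LungState", "init_state", "lung_rates", "ideal_gas_residual"]


@dataclass(frozen=True)
class LungParameters:
    """Static parameters of one lung.

    Attributes
    ----------
    C : float
        Respiratory compliance, mL/cmH2O (clinical units; converted to
        m^3/Pa internally via :attr:`C_si`).
    throttle : ThrottleGeometry
        Equivalent inlet throttle.
    V0 : float
        Initial (resting) gas volume, L.  Not stated by typical bench
        descriptions; 1.5 L is a plausible adult lung-simulator scale.
    """

    C: float = 10.0
    throttle: ThrottleGeometry = field(default_factory=ThrottleGeometry)
    V0: float = 1.5

    def __post_init__(self) -> None:
        if not self.C > 0:
            raise ValueError(f"compliance must be positive, got {self.C} mL/cmH2O")
        if not self.V0 > 0:
            raise ValueError(f"initial volume must be positive, got {self.V0} L")

    @property
    def C_si(self) -> float:
        """Compliance in SI units, m^3/Pa."""
        return self.C * 1e-6 / CMH2O_TO_PA

    @property
    def V0_si(self) -> float:
        """Initial volume in m^3."""
        return self.V0 * 1e-3


@dataclass
class LungState:
    """Instantaneous gas state of one lung (SI units).

    p : absolute pressure, Pa; V : volume, m^3; m : gas mass, kg.
    """

    p: float
    V: float
    m: float

    def __post_init__(self) -> None:
        if not (self.p > 0 and self.V > 0 and self.m > 0):
            raise ValueError(
                f"lung state must be positive, got p={self.p}, V={self.V}, m={self.m}"
            )


def init_state(
    params: LungParameters, gas: GasProperties, p_start: float
) -> LungState:
    """Initial lung state at gauge pressure ``p_start`` (cmH2O).

    The mass is closed through the gas law ``m = p V / (R theta)`` so the
    ideal-gas residual starts exactly at zero.
    """
    p = cmh2o_to_pa_abs(p_start)
    V = params.V0_si
    m = p * V / (gas.R_specific * gas.theta)
    return LungState(p=p, V=V, m=m)


def lung_rates(
    state: LungState,
    q: float,
    params: LungParameters,
    gas: GasProperties,
) -> tuple[float, float, float]:
    """Time derivatives (dp/dt, dV/dt, dm/dt) for mass inflow ``q`` (kg/s)."""
    Rtheta = gas.R_specific * gas.theta
    C = params.C_si
    dp = Rtheta * q * state.V / (state.V**2 + C * state.m * Rtheta)
    return dp, C * dp, q


def ideal_gas_residual(state: LungState, gas: GasProperties) -> float:
    """Relative departure from the gas law, ``(pV - m R theta)/(pV)``.

    Zero for a consistent state; along a simulated trajectory its drift
    measures integrator error, since the gas law is an exact invariant of
    the dynamics.
    """
    pv = state.p * state.V
    return (pv - state.m * gas.R_specific * gas.theta) / pv
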