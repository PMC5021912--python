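"""Gas constants, unit conventions, and compressible orifice mass flow.

Everything downstream of the configuration boundary works in SI units:
absolute pressure in Pa, volume in m^3, mass in kg, time in s, temperature
in K.  Clinical units (cmH2O gauge, mm, mL, breaths/min) appear only in
configuration objects and report writers; the converters here define the
conventions once.

The orifice law is the standard compressible flow-through-a-nozzle
relation: below the critical downstream/upstream pressure ratio
``b = (2/(k+1))**(k/(k-1))`` the flow is choked (sonic) and independent of
downstream pressure; above it the subsonic expression applies.  The two
branches coincide at ``b``, so mass flow is continuous in the pressure
ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np

__all__ = [
    "CMH2O_TO_PA",
    "P_ATM_PA",
    "GasProperties",
    "ThrottleGeometry",
    "critical_pressure_ratio",
    "cmh2o_to_pa_abs",
    "pa_abs_to_cmh2o",
    "orifice_mass_flow",
]

#: Pa per cmH2O (conventional value).
CMH2O_TO_PA = 98.0665
#: Standard atmosphere, Pa; gauge pressures are referenced to it.
P_ATM_PA = 101325.0


def critical_pressure_ratio(k: float) -> float:
    """Critical (choking) downstream/upstream pressure ratio for a perfect gas.

    Parameters
    ----------
    k : float
        Ratio of specific heats, strictly greater than 1.

    Returns
    -------
    float
        ``(2/(k+1))**(k/(k-1))``; for air (k = 1.4) this is about 0.5283.
        The subsonic and sonic flow expressions agree exactly at this ratio.
    """
    if not k > 1.0:
        raise ValueError(f"heat-capacity ratio must exceed 1, got k={k}")
    return (2.0 / (k + 1.0)) ** (k / (k - 1.0))


@dataclass(frozen=True)
class GasProperties:
    """Properties of the ventilated gas (dry air by default).

    Attributes
    ----------
    R_specific : float
        Specific gas constant, J/(kg K).
    k : float
        Ratio of specific heats (dimensionless).
    theta : float
        Absolute temperature, K.  The breathing cycle is treated as
        isothermal, so a single temperature enters both the flow law and
        the lung gas law.
    b : float
        Critical pressure ratio; derived from ``k`` unless given explicitly.
    """

    R_specific: float = 287.05
    k: float = 1.4
    theta: float = 293.15
    b: float = field(default=math.nan)

    def __post_init__(self) -> None:
        if not self.R_specific > 0:
            raise ValueError("R_specific must be positive")
        if not self.k > 1:
            raise ValueError("k must exceed 1")
        if not self.theta > 0:
            raise ValueError("theta must be positive")
        if math.isnan(self.b):
            object.__setattr__(self, "b", critical_pressure_ratio(self.k))
        if not 0.0 < self.b < 1.0:
            raise ValueError("critical pressure ratio must lie in (0, 1)")


@dataclass(frozen=True)
class ThrottleGeometry:
    """Equivalent throttle (lumped airway/tube resistance) geometry.

    Attributes
    ----------
    d : float
        Inlet diameter of the effective area, mm.
    Cd : float
        Discharge coefficient in (0, 1]; default 1 treats the quoted
        diameter as the fully effective diameter.
    """

    d: float = 3.2
    Cd: float = 1.0

    def __post_init__(self) -> None:
        if not self.d > 0:
            raise ValueError(f"throttle diameter must be positive, got {self.d} mm")
        if not 0.0 < self.Cd <= 1.0:
            raise ValueError(f"discharge coefficient must lie in (0, 1], got {self.Cd}")

    @property
    def Ae(self) -> float:
        """Effective flow area Cd * pi * (d/2)^2, m^2."""
        return self.Cd * math.pi * (self.d * 1e-3 / 2.0) ** 2


def cmh2o_to_pa_abs(p_gauge, /):
    """Convert cmH2O gauge pressure to absolute pressure in Pa.

    Accepts scalars or arrays.  Raises if the absolute result is not
    positive (gauge below full vacuum).
    """
    p = np.asarray(p_gauge, dtype=float) * CMH2O_TO_PA + P_ATM_PA
    if np.any(p <= 0.0):
        raise ValueError("absolute pressure must be positive")
    return float(p) if np.isscalar(p_gauge) or np.ndim(p_gauge) == 0 else p


def pa_abs_to_cmh2o(p_abs, /):
    """Inverse of :func:`cmh2o_to_pa_abs`."""
    p = np.asarray(p_abs, dtype=float)
    if np.any(p <= 0.0):
        raise ValueError("absolute pressure must be positive")
    out = (p - P_ATM_PA) / CMH2O_TO_PA
    return float(out) if np.ndim(p_abs) == 0 else out


def orifice_mass_flow(p_up, p_down, Ae, gas: GasProperties):
    """Signed compressible mass flow through an orifice, kg/s.

    Flow follows the pressure gradient: positive from the nominal upstream
    port toward the nominal downstream port, negative when the gradient is
    reversed, so one throttle carries both inspiration and expiration.
    With pressure ratio r = min(p)/max(p):

    * subsonic (r > b):
      ``q = Ae * p_max * sqrt(1/theta) * sqrt(2k/(k-1) / R * (r^(2/k) - r^((k+1)/k)))``
    * choked (r <= b): the same expression frozen at ``r = b``; the mass
      flow no longer depends on the downstream pressure.

    Parameters
    ----------
    p_up, p_down : float or ndarray
        Absolute pressures at the two ports, Pa (broadcastable).
    Ae : float
        Effective orifice area, m^2 (non-negative).
    gas : GasProperties
        Gas constants and temperature.
    """
    pu = np.asarray(p_up, dtype=float)
    pd_ = np.asarray(p_down, dtype=float)
    if np.any(pu <= 0.0) or np.any(pd_ <= 0.0):
        raise ValueError("orifice pressures must be positive absolute pressures")
    if Ae < 0.0:
        raise ValueError("effective area must be non-negative")

    hi = np.maximum(pu, pd_)
    lo = np.minimum(pu, pd_)
    sign = np.where(pu >= pd_, 1.0, -1.0)
    # clamping the ratio at b gives the choked plateau and keeps the
    # expression continuous at the sonic/subsonic boundary
    r = np.maximum(lo / hi, gas.b)
    k = gas.k
    expansion = r ** (2.0 / k) - r ** ((k + 1.0) / k)
    flux = hi * np.sqrt(1.0 / gas.theta) * np.sqrt(
        (2.0 * k / (k - 1.0)) / gas.R_specific * expansion
    )
    q = sign * Ae * flux
    if np.ndim(q) == 0:
        return float(q)
    return q
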