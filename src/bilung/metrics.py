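"""Flow-split and tidal-volume-share metrics.

Two quantities summarise how the two lungs share the delivered gas:

* the instantaneous flow-split ratio ``q_r / q_s`` (fraction of total mass
  flow entering — or leaving — the right lung), and
* the per-breath tidal-volume share ``VT_r / VT_s``, where the tidal
  volume ``VT_i`` is the volume excursion (max - min of ``V_i``) of lung
  ``i`` over one cycle and ``VT_s = VT_r + VT_l``.

The flow ratio is ill-conditioned where the total flow crosses zero
(phase switches); those samples are masked out rather than clamped.  Near
a switch the two lung flows can briefly carry opposite signs (gas
redistributing between compartments with unequal time constants), so
unmasked values may legitimately fall outside [0, 1]; they are reported
raw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import CycleSegment, Trajectory, segment_cycles

__all__ = [
    "FlowRatioSeries",
    "BreathMetrics",
    "flow_ratio_series",
    "tidal_volumes",
    "metrics_frame",
    "sweep_summary",
]

#: Default total-flow floor below which the ratio is masked, kg/s
#: (roughly 0.005 L/min of air at ambient density).
DEFAULT_EPS = 1e-7


@dataclass
class FlowRatioSeries:
    """Time series of q_r/q_s with a validity mask.

    ``ratio`` holds NaN where ``valid`` is False (|q_s| at or below the
    floor ``eps``).  Values are fractions; multiply by 100 to report
    percent as clinical figures do.
    """

    t: np.ndarray
    ratio: np.ndarray
    valid: np.ndarray
    eps: float

    @property
    def masked_fraction(self) -> float:
        return 1.0 - float(np.count_nonzero(self.valid)) / self.valid.size

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "ratio": self.ratio, "valid": self.valid})


@dataclass
class BreathMetrics:
    """Per-cycle tidal volumes and the right-lung share.

    Volumes are in mL.  ``vt_share_r`` is a fraction in [0, 1]; it is NaN
    (and ``degenerate`` True) when the breath moved no gas at all.
    """

    cycle: int
    VT_r: float
    VT_l: float
    VT_s: float
    vt_share_r: float
    degenerate: bool = False


def flow_ratio_series(traj: Trajectory, eps: float = DEFAULT_EPS) -> FlowRatioSeries:
    """Instantaneous flow-split ratio q_r/q_s with near-zero-flow masking."""
    if eps < 0:
        raise ValueError("eps must be non-negative")
    valid = np.abs(traj.q_s) > eps
    ratio = np.full_like(traj.q_s, np.nan)
    np.divide(traj.q_r, traj.q_s, out=ratio, where=valid)
    return FlowRatioSeries(t=traj.t, ratio=ratio, valid=valid, eps=eps)


def tidal_volumes(
    traj: Trajectory, cycles: list[CycleSegment] | None = None
) -> list[BreathMetrics]:
    """Per-cycle tidal volumes and right-lung share from volume excursions."""
    cycles = cycles if cycles is not None else segment_cycles(traj)
    out = []
    for i, seg in enumerate(cycles):
        V_r = traj.V_r[seg.full]
        V_l = traj.V_l[seg.full]
        vt_r = float(V_r.max() - V_r.min()) * 1e6
        vt_l = float(V_l.max() - V_l.min()) * 1e6
        vt_s = vt_r + vt_l
        if vt_s > 0:
            share, degenerate = vt_r / vt_s, False
        else:
            share, degenerate = float("nan"), True
        out.append(
            BreathMetrics(
                cycle=i, VT_r=vt_r, VT_l=vt_l, VT_s=vt_s,
                vt_share_r=share, degenerate=degenerate,
            )
        )
    return out


def metrics_frame(metrics: list[BreathMetrics]) -> pd.DataFrame:
    """Tabulate per-cycle metrics (volumes in mL, share as a fraction)."""
    return pd.DataFrame(
        {
            "cycle": [m.cycle for m in metrics],
            "VT_r_mL": [m.VT_r for m in metrics],
            "VT_l_mL": [m.VT_l for m in metrics],
            "VT_s_mL": [m.VT_s for m in metrics],
            "vt_share_r": [m.vt_share_r for m in metrics],
        }
    )


def _phase_extrema(ratios: FlowRatioSeries, phase: slice) -> tuple[float, float]:
    r = ratios.ratio[phase]
    v = ratios.valid[phase]
    if not v.any():
        return float("nan"), float("nan")
    return float(np.nanmin(r[v])), float(np.nanmax(r[v]))


def sweep_summary(
    parameter: str,
    results: list[tuple[float, Trajectory]],
    eps: float = DEFAULT_EPS,
) -> pd.DataFrame:
    """One-row-per-scenario summary of a one-dimensional parameter sweep.

    For each (swept value, trajectory) pair the last recorded cycle
    yields the tidal-volume share and the flow-ratio extrema of the
    inspiratory and expiratory phases.  Rows are sorted by swept value.

    Raises if the result list is empty (mixed sweep dimensions cannot be
    tabulated together; callers pass one parameter name per table).
    """
    if not results:
        raise ValueError("sweep summary needs at least one scenario")
    rows = []
    for value, traj in sorted(results, key=lambda vt: vt[0]):
        cycles = segment_cycles(traj)
        last = cycles[-1]
        bm = tidal_volumes(traj, [last])[0]
        ratios = flow_ratio_series(traj, eps=eps)
        insp_min, insp_max = _phase_extrema(ratios, last.inspiration)
        exp_min, exp_max = _phase_extrema(ratios, last.expiration)
        rows.append(
            {
                "parameter": parameter,
                "value": value,
                "VT_r_mL": bm.VT_r,
                "VT_l_mL": bm.VT_l,
                "VT_s_mL": bm.VT_s,
                "vt_share_r": bm.vt_share_r,
                "insp_ratio_min": insp_min,
                "insp_ratio_max": insp_max,
                "exp_ratio_min": exp_min,
                "exp_ratio_max": exp_max,
                "steady": traj.steady,
            }
        )
    return pd.DataFrame(rows)
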