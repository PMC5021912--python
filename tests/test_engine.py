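"""Coupled-system integration: symmetry, conservation, segmentation."""

from dataclasses import replace

import numpy as np
import pytest

from bilung import (
    GasProperties,
    SimulationConfig,
    apply_parameter,
    cmh2o_to_pa_abs,
    reference_scenario,
    segment_cycles,
    system_derivatives,
)
from bilung.engine import _make_rhs

QUICK = dict(n_warmup_cycles=2, n_record_cycles=1)


def quick(scenario):
    return replace(scenario, sim=replace(scenario.sim, **QUICK))


class TestSystemDerivatives:
    def test_equilibrium_is_stationary(self, ref_scenario, gas):
        s = ref_scenario
        p_eq = cmh2o_to_pa_abs(22.0)  # setpoint during the plateau
        V = s.lung_r.V0_si
        m = p_eq * V / (gas.R_specific * gas.theta)
        y = np.array([p_eq, V, m, p_eq, V, m])
        dy = system_derivatives(0.5, y, s.settings, s.lung_r, s.lung_l, gas)
        np.testing.assert_array_equal(dy, np.zeros(6))

    def test_identical_lungs_identical_rates(self, ref_scenario, gas):
        s = ref_scenario
        y = np.array([1.02e5, 1.5e-3, 1.8e-3] * 2)
        dy = system_derivatives(1.7, y, s.settings, s.lung_r, s.lung_l, gas)
        np.testing.assert_array_equal(dy[:3], dy[3:])

    def test_fast_rhs_matches_reference_implementation(self, ref_scenario, gas):
        """The scalar hot-path rhs must agree with the readable composed
        one to machine precision at random states and times."""
        s = ref_scenario
        rhs = _make_rhs(s.settings, s.lung_r, s.lung_l, gas)
        rng = np.random.default_rng(7)
        for _ in range(100):
            p = rng.uniform(0.99e5, 1.05e5, 2)
            V = rng.uniform(1e-3, 2e-3, 2)
            m = p * V / (gas.R_specific * gas.theta) * rng.uniform(0.99, 1.01, 2)
            y = np.array([p[0], V[0], m[0], p[1], V[1], m[1]])
            t = rng.uniform(0.0, 3.0)
            slow = system_derivatives(t, y, s.settings, s.lung_r, s.lung_l, gas)
            np.testing.assert_allclose(rhs(t, y), slow, rtol=1e-12)


class TestSimulate:
    def test_symmetric_lungs_share_flow_exactly(self, ref_traj):
        """Two identical lungs fed from one node follow identical
        trajectories, so the flows match sample for sample."""
        np.testing.assert_array_equal(ref_traj.q_r, ref_traj.q_l)
        np.testing.assert_array_equal(ref_traj.p_r_pa, ref_traj.p_l_pa)

    def test_total_flow_is_sum_exactly(self, ref_traj):
        np.testing.assert_array_equal(ref_traj.q_s, ref_traj.q_r + ref_traj.q_l)

    def test_swap_relabels_exactly(self, ref_scenario):
        """Exchanging the two lung parameter blocks relabels the
        trajectory bit for bit (no hidden asymmetry in the engine)."""
        a = quick(apply_parameter(ref_scenario, "C_r", 8.0))
        b = replace(a, lung_r=a.lung_l, lung_l=a.lung_r)
        ta, tb = a.run(), b.run()
        np.testing.assert_array_equal(ta.p_r_pa, tb.p_l_pa)
        np.testing.assert_array_equal(ta.p_l_pa, tb.p_r_pa)
        np.testing.assert_array_equal(ta.V_r, tb.V_l)
        np.testing.assert_array_equal(ta.q_r, tb.q_l)

    def test_constant_pressure_source_gives_no_ventilation(self, ref_scenario):
        s = replace(
            ref_scenario,
            settings=replace(ref_scenario.settings, IPAP=4.0, EPAP=4.0),
        )
        traj = quick(s).run()
        assert np.abs(traj.q_s).max() < 1e-12
        assert traj.V_r.max() - traj.V_r.min() < 1e-12

    def test_gas_law_residual_stays_small(self, ref_traj):
        res_r, res_l = ref_traj.ideal_gas_residuals()
        assert np.abs(res_r).max() < 1e-6
        assert np.abs(res_l).max() < 1e-6

    def test_mass_bookkeeping_matches_flow_integral(self, ref_traj):
        """m(t) - m(0) reconstructed by trapezoid quadrature of q on the
        1 ms output grid; the bound reflects grid quadrature error across
        the waveform kinks, the integrator itself is far tighter."""
        t = ref_traj.t
        for m, q in ((ref_traj.m_r, ref_traj.q_r), (ref_traj.m_l, ref_traj.q_l)):
            integral = np.concatenate(
                ([0.0], np.cumsum((q[1:] + q[:-1]) / 2) * np.diff(t))
            )
            inspired = np.trapezoid(np.clip(q, 0.0, None), t) / ref_traj.n_cycles
            assert np.abs((m - m[0]) - integral).max() < 0.01 * inspired

    def test_steady_flag_on_reference(self, ref_traj):
        assert ref_traj.steady

    def test_unsteady_warmup_warns(self, ref_scenario):
        """With an unreachable steadiness threshold the engine flags and
        warns but still returns the trajectory."""
        s = replace(
            ref_scenario,
            sim=replace(ref_scenario.sim, steady_tol=1e-16, **QUICK),
        )
        with pytest.warns(RuntimeWarning, match="warm-up"):
            traj = s.run()
        assert not traj.steady

    def test_output_grid_uniform(self, ref_traj):
        dt = np.diff(ref_traj.t)
        assert np.allclose(dt, ref_traj.t[1] - ref_traj.t[0], rtol=0, atol=1e-12)
        assert ref_traj.t[0] == 0.0

    def test_dataframe_units(self, ref_traj):
        clin = ref_traj.to_dataframe("clinical")
        si = ref_traj.to_dataframe("si")
        assert clin.V_r.max() == pytest.approx(si.V_r.max() * 1e6)
        assert clin.p_vent.max() == pytest.approx(22.0)
        with pytest.raises(ValueError):
            ref_traj.to_dataframe("imperial")


class TestSimulationConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_record_cycles": 0},
            {"rel_tol": 0.0},
            {"output_dt": -1e-3},
            {"max_step": 0.0},
        ],
    )
    def test_invalid_config(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestSegmentCycles:
    def test_three_cycles_of_3000_samples(self, ref_traj):
        segs = segment_cycles(ref_traj)
        assert len(segs) == 3
        assert all(s.end - s.start == 3000 for s in segs)

    def test_inspiration_duration_is_ti(self, ref_traj):
        for s in segment_cycles(ref_traj):
            n_insp = s.insp_end - s.start
            assert n_insp == 1000  # Ti = 1 s on a 1 ms grid

    def test_ranges_tile_trajectory(self, ref_traj):
        segs = segment_cycles(ref_traj)
        assert segs[0].start == 0
        assert segs[-1].end == ref_traj.t.size
        for a, b in zip(segs[:-1], segs[1:]):
            assert a.end == b.start

    def test_short_trajectory_rejected(self, ref_traj):
        stub = replace(
            ref_traj,
            t=ref_traj.t[:100],
            V_r=ref_traj.V_r[:100],
            V_l=ref_traj.V_l[:100],
        )
        with pytest.raises(ValueError):
            segment_cycles(stub)
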