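"""Line-level interconnection: splitting, mixing, scheduling, full simulation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import fbdry
from fbdry.cell import Phase
from fbdry.line import (
    LineParams,
    LineSchedule,
    SolverOptions,
    Timeline,
    emptying_air_flow,
    granule_feed_streams,
    mix_streams,
    net_inlet_mixing,
    outlet_mixing,
    split_inlet,
    step_schedule,
)
from fbdry.psychro import MoistAirConstants, humid_enthalpy

C = MoistAirConstants()


class TestSplitInlet:
    def test_division_by_six(self):
        assert split_inlet(0.12) == pytest.approx(0.02)

    def test_sum_of_splits_equals_total(self):
        assert 6 * split_inlet(0.123456) == pytest.approx(0.123456, rel=1e-15)

    def test_zero(self):
        assert split_inlet(0.0) == 0.0


class TestGranuleFeedStreams:
    def test_unit_conversion(self):
        gi, wi = granule_feed_streams(20.0, 40.0, 0.0)
        assert gi == pytest.approx(20.0 / 3600.0)
        assert wi == pytest.approx(0.040 / 60.0)

    def test_dry_feed_only(self):
        gi, wi = granule_feed_streams(20.0, 0.0, 0.0)
        assert wi == 0.0 and gi > 0

    @given(mp=st.floats(0.0, 100.0), ml=st.floats(0.0, 500.0),
           wp=st.floats(0.0, 50.0))
    def test_total_wet_mass_conserved(self, mp, ml, wp):
        gi, wi = granule_feed_streams(mp, ml, wp)
        assert gi + wi == pytest.approx(mp / 3600.0 + ml / 60000.0, rel=1e-12, abs=1e-15)

    def test_invalid_wp_rejected(self):
        with pytest.raises(ValueError):
            granule_feed_streams(20.0, 40.0, 100.0)


class TestEmptyingAirFlow:
    def test_frozen_arithmetic(self):
        params = LineParams()
        got = emptying_air_flow(0.12, 6.56e-3, params)
        assert got == pytest.approx(0.12 / 35 + 0.13 * 6.56e-3, rel=1e-12)
        assert got == pytest.approx(4.2814e-3, rel=1e-3)

    def test_zero_inputs(self):
        assert emptying_air_flow(0.0, 0.0, LineParams()) == 0.0

    def test_phase_gate(self):
        assert emptying_air_flow(0.12, 6.56e-3, LineParams(), Phase.DRYING) == 0.0


class TestNetInletMixing:
    def test_single_stream_identity(self):
        m, T, x = net_inlet_mixing(Phase.DRYING, 0.02, 45.0, 0.006)
        assert (m, T, x) == (pytest.approx(0.02), pytest.approx(45.0),
                             pytest.approx(0.006))

    def test_equal_flows_average_temperature(self):
        # equal dry-air flows at equal x: enthalpy is linear in T, so the
        # mixed temperature is the arithmetic mean
        m, T, x = mix_streams([0.01, 0.01], [20.0, 40.0], [0.005, 0.005])
        assert T == pytest.approx(30.0, rel=1e-12)
        assert x == pytest.approx(0.005)

    def test_zero_total_flow_is_configuration_error(self):
        with pytest.raises(ValueError):
            mix_streams([0.0, 0.0], [20.0, 40.0], [0.005, 0.005])

    @given(st.lists(st.tuples(st.floats(1e-4, 0.1), st.floats(5.0, 60.0),
                              st.floats(0.0, 0.05)), min_size=2, max_size=4))
    def test_water_flux_conserved(self, streams):
        flows, Ts, xs = zip(*streams)
        m, T, x = mix_streams(flows, Ts, xs)
        assert m * x == pytest.approx(sum(f * xi for f, xi in zip(flows, xs)),
                                      rel=1e-12)

    def test_transport_air_joins_only_during_filling(self):
        transport = (0.005, 20.0, 0.006)
        m_fill, _, _ = net_inlet_mixing(Phase.FILLING, 0.02, 45.0, 0.006,
                                        transport=transport)
        m_dry, _, _ = net_inlet_mixing(Phase.DRYING, 0.02, 45.0, 0.006,
                                       transport=transport)
        assert m_fill == pytest.approx(0.025)
        assert m_dry == pytest.approx(0.02)


class TestOutletMixing:
    def test_identical_streams_pass_through(self):
        m = np.full(6, 0.02)
        x = np.full(6, 0.011)
        T = np.full(6, 33.0)
        m_t, x_t, T_t = outlet_mixing(m, x, T)
        assert m_t == pytest.approx(0.12)
        assert x_t == pytest.approx(0.011)
        assert T_t == pytest.approx(33.0, rel=1e-12)

    @given(st.integers(0, 2**31 - 1))
    def test_enthalpy_closure_on_random_streams(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.uniform(1e-3, 0.05, 6)
        x = rng.uniform(0.0, 0.08, 6)
        T = rng.uniform(5.0, 70.0, 6)
        m_t, x_t, T_t = outlet_mixing(m, x, T)
        lhs = m_t * humid_enthalpy(T_t, x_t, C)
        rhs = float(np.sum(m * humid_enthalpy(T, x, C)))
        assert lhs == pytest.approx(rhs, rel=1e-10)
        assert m_t * x_t == pytest.approx(float(np.sum(m * x)), rel=1e-12)

    def test_zero_flow_rejected(self):
        with pytest.raises(ValueError):
            outlet_mixing(np.zeros(6), np.zeros(6), np.zeros(6))


class TestSchedule:
    def test_cold_start_first_cell_filling(self, one_cycle_inputs):
        phases = step_schedule(10.0, LineSchedule(), one_cycle_inputs)
        assert phases[0] is Phase.FILLING
        assert all(p is Phase.IDLE for p in phases[1:])

    def test_drying_then_emptying_sequence(self, one_cycle_inputs):
        tl = Timeline(LineSchedule(), one_cycle_inputs, t_end=1100.0)
        # cell 1 fills [0, 180), dries 580 s, then empties for 30 s
        assert tl.phase_of(0, 100.0) is Phase.FILLING
        assert tl.phase_of(0, 200.0) is Phase.DRYING
        assert tl.phase_of(0, 180.0 + 580.0 + 1.0) is Phase.EMPTYING
        assert tl.phase_of(0, 180.0 + 580.0 + 31.0) is Phase.IDLE
        assert tl.blowback_active(0, 180.0 + 580.0 + 5.0)
        assert not tl.blowback_active(0, 180.0 + 580.0 + 15.0)

    def test_rotation_periodic_at_1080_s(self):
        # with tdry = 580 s <= 5*180 s the calendar repeats every 6*180 s
        steps = (fbdry.ExperimentStep(0.0, 4000.0, 20, 40, 45, 300, 580),)
        inputs = fbdry.build_inputs(steps)
        tl = Timeline(LineSchedule(), inputs, t_end=4000.0)
        # steady operation: skip the cold-start rotation, where not-yet
        # filled cells are still idle
        for t in np.arange(1080.0, 2900.0, 7.0):
            assert tl.phases_at(t) == tl.phases_at(t + 1080.0)

    def test_overlong_drying_warns(self):
        steps = (fbdry.ExperimentStep(0.0, 2000.0, 20, 40, 45, 300, 880.0),)
        inputs = fbdry.build_inputs(steps)
        with pytest.warns(UserWarning, match="rotation"):
            Timeline(LineSchedule(), inputs, t_end=2000.0)


class TestSimulateLine:
    def test_no_feed_run_is_all_masked_and_near_inlet(self):
        steps = (fbdry.ExperimentStep(0.0, 1200.0, 0.0, 0.0, 45, 300, 580),)
        inputs = fbdry.build_inputs(steps)
        traj = fbdry.simulate_line(inputs, solver=SolverOptions(dt_out=5.0))
        assert np.all(np.isnan(traj.lod))
        # outlet air equals inlet air up to the small wall loss
        u = inputs.at(0.0)
        assert traj.x_ao_t[-1] == pytest.approx(traj.x_ai_net[-1, 0], rel=1e-9)
        assert traj.T_ao_t[-1] < u["T_ai"]
        assert traj.T_ao_t[-1] == pytest.approx(u["T_ai"], abs=2.0)

    def test_dry_air_balance_at_line_level(self, short_trajectory):
        traj = short_trajectory
        blowing = np.any(traj.mdot_ae > 0, axis=1)
        # outside blowback/emptying the per-cell net inlets sum to the AHU flow
        quiet = ~np.any(traj.phase == 2, axis=1)
        assert traj.mdot_ai_net[quiet].sum(axis=1) == pytest.approx(
            traj.mdot_ai_t[quiet], rel=1e-12)
        # the plenum flow plus the emptying stream always equals the net inlet
        assert traj.mdot_ao_t + traj.mdot_ae.sum(axis=1) == pytest.approx(
            traj.mdot_ai_net.sum(axis=1), rel=1e-12)

    def test_water_and_energy_balances_close(self, short_trajectory):
        wb = short_trajectory.water_balance()
        eb = short_trajectory.energy_balance()
        assert abs(wb["relative_residual"]) < 1e-6
        assert abs(eb["relative_residual"]) < 1e-6

    def test_grid_refinement_leaves_lod_unchanged(self, one_cycle_inputs):
        opts = dict(rtol=1e-8, atol=1e-10)
        a = fbdry.simulate_line(one_cycle_inputs, solver=SolverOptions(dt_out=2.0, **opts))
        b = fbdry.simulate_line(one_cycle_inputs, solver=SolverOptions(dt_out=1.0, **opts))
        lod_a = a.lod[:, 0]
        lod_b = b.lod[::2, 0]
        both = np.isfinite(lod_a) & np.isfinite(lod_b)
        assert np.max(np.abs(lod_a[both] - lod_b[both])) < 1e-3

    def test_permutation_symmetry(self, one_cycle_inputs):
        solver = SolverOptions(dt_out=5.0, rtol=1e-8, atol=1e-10)
        base = fbdry.simulate_line(one_cycle_inputs, solver=solver)
        order = (2, 0, 1, 3, 4, 5)
        permuted = fbdry.simulate_line(
            one_cycle_inputs, schedule=LineSchedule(cell_order=order), solver=solver)
        # the first fill slot now belongs to cell 3: its trajectory must
        # replicate cell 1 of the identity ordering exactly
        np.testing.assert_allclose(permuted.mw[:, 2], base.mw[:, 0], atol=1e-12)
        np.testing.assert_allclose(permuted.Tg[:, 2], base.Tg[:, 0], atol=1e-10)

    def test_higher_airflow_dries_faster(self):
        ends = []
        for V in (260.0, 400.0):
            steps = (fbdry.ExperimentStep(0.0, 900.0, 20, 40, 45, V, 580),)
            traj = fbdry.simulate_line(fbdry.build_inputs(steps),
                                       solver=SolverOptions(dt_out=5.0))
            drying = traj.phase_mask(0, Phase.DRYING)
            ends.append(traj.lod[drying, 0][-1])
        assert ends[1] < ends[0]
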