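"""Single dryer-cell dynamics: transfer closures, state reconstruction, sensor."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from fbdry.cell import (
    CellInputs,
    CellParams,
    CellState,
    Phase,
    air_temperature,
    empty_reset,
    evaporation_rate,
    granule_temperature,
    heat_flow_air_to_granules,
    heat_loss,
    lod,
    sensor_temperature,
    state_derivatives,
)
from fbdry.psychro import (
    AirState,
    MoistAirConstants,
    humid_enthalpy,
    saturation_vapor_pressure,
    water_content_from_rh,
)

C = MoistAirConstants()


class TestHeatFlows:
    def test_zero_driving_force(self):
        k1 = 0.381
        Tg = (1 - k1) * 45.0 + k1 * 30.0
        assert heat_flow_air_to_granules(45.0, 30.0, Tg, k1, 3.22) == pytest.approx(0.0)

    def test_table_arithmetic(self):
        got = heat_flow_air_to_granules(45.0, 30.0, 25.0, 0.381, 3.22)
        assert got == pytest.approx(3.22 * ((0.619 * 45 + 0.381 * 30) - 25), rel=1e-12)

    def test_linear_in_coefficient(self):
        a = heat_flow_air_to_granules(45.0, 30.0, 25.0, 0.381, 3.22)
        b = heat_flow_air_to_granules(45.0, 30.0, 25.0, 0.381, 6.44)
        assert b == pytest.approx(2 * a, rel=1e-14)

    def test_wall_loss(self):
        # blend at 40 degC, ambient 20 degC, kloss from the identified set
        assert heat_loss(40.0, 40.0, 20.0, 0.381, 0.353) == pytest.approx(7.06)
        assert heat_loss(25.0, 25.0, 25.0, 0.5, 0.353) == 0.0
        assert heat_loss(40.0, 40.0, 20.0, 0.381, 0.0) == 0.0


class TestEvaporationRate:
    def test_no_water_no_evaporation(self):
        air = AirState(T=45.0, phi=0.2)
        assert evaporation_rate(0.0, air, 0.02, 1.77e-5) == 0.0

    def test_saturated_inlet_stops_drying(self):
        air = AirState(T=45.0, phi=1.0)
        assert evaporation_rate(1.0, air, 0.02, 1.77e-5) == pytest.approx(0.0, abs=1e-15)

    def test_supersaturated_inlet_floored_at_zero(self):
        air = AirState(T=45.0, phi=1.2)
        assert evaporation_rate(1.0, air, 0.02, 1.77e-5) == 0.0

    def test_frozen_arithmetic(self):
        # (pv_s - pv) = 7.67e3 Pa at 45 degC and ~20 % RH
        phi = 1.0 - 7.67e3 / saturation_vapor_pressure(45.0)
        air = AirState(T=45.0, phi=phi)
        got = evaporation_rate(1.0, air, 0.0202, 1.77e-5)
        assert got == pytest.approx(2.7423e-3, rel=1e-4)


class TestStateReconstruction:
    def test_granule_temperature_round_trip(self):
        mg, mw, Tg = 1.7, 0.3, 31.5
        Ugw = mg * 1300.0 * Tg + mw * C.cw * Tg
        assert granule_temperature(mg, mw, Ugw, 1300.0, C.cw) == pytest.approx(
            Tg, rel=1e-12)

    def test_zero_energy_is_reference_temperature(self):
        assert granule_temperature(1.0, 0.0, 0.0, 1300.0, C.cw) == 0.0

    def test_empty_cell_uses_fallback(self):
        assert granule_temperature(0.0, 0.0, 0.0, 1300.0, C.cw, fallback=42.0) == 42.0
        with pytest.raises(ValueError):
            granule_temperature(0.0, 0.0, 0.0, 1300.0, C.cw)

    def test_air_temperature_round_trip(self):
        ma, xa, Ta = 0.197, 0.015, 38.0
        Uav = ma * (C.cp_a * Ta + xa * (C.cp_v * Ta + C.dhe))
        assert air_temperature(Uav, xa, ma, C) == pytest.approx(Ta, rel=1e-12)

    def test_latent_only_energy_is_zero_celsius(self):
        ma, xa = 0.197, 0.01
        assert air_temperature(ma * xa * C.dhe, xa, ma, C) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("mw, mg, expected", [
        (0.1, 0.9, 10.0), (0.0, 1.0, 0.0), (0.5, 0.5, 50.0),
    ])
    def test_lod(self, mw, mg, expected):
        assert lod(mw, mg) == pytest.approx(expected)

    def test_lod_empty_cell_masked(self):
        assert math.isnan(lod(0.0, 0.0))


class TestEmptyReset:
    def test_reset_clears_granules_keeps_air(self):
        s = CellState(mg=2.0, mw=0.3, xa=0.02, Ugw=9.9e4, Uav=1.2e4)
        r = empty_reset(s)
        assert (r.mg, r.mw, r.Ugw) == (0.0, 0.0, 0.0)
        assert (r.xa, r.Uav) == (s.xa, s.Uav)

    def test_idempotent(self):
        s = empty_reset(CellState(mg=2.0, mw=0.3, xa=0.02, Ugw=9.9e4, Uav=1.2e4))
        assert empty_reset(s) == s

    def test_lod_after_reset_is_masked(self):
        r = empty_reset(CellState(mg=2.0, mw=0.3))
        assert math.isnan(lod(r.mw, r.mg))


def _equilibrium_setup():
    params = CellParams()
    T, p = 40.0, 101325.0
    x = water_content_from_rh(0.3, T, p)
    inputs = CellInputs(mdot_ai_net=0.02, T_ai_net=T, x_ai_net=x, T_aa=T, p=p)
    state = CellState(mg=1.0, mw=0.0, xa=x,
                      Ugw=1.0 * params.cg * T,
                      Uav=params.ma * humid_enthalpy(T, x))
    return state, inputs, params


class TestStateDerivatives:
    def test_thermal_equilibrium_is_fixed_point(self):
        state, inputs, params = _equilibrium_setup()
        dy = state_derivatives(state, inputs, params, Phase.DRYING)
        assert np.allclose(dy, 0.0, atol=1e-9)

    def test_negative_state_rejected(self):
        state, inputs, params = _equilibrium_setup()
        bad = CellState(mg=1.0, mw=-0.1, xa=state.xa, Ugw=state.Ugw, Uav=state.Uav)
        with pytest.raises(ValueError):
            state_derivatives(bad, inputs, params, Phase.DRYING)

    def test_water_decays_exponentially_without_feed(self):
        # constant inlet air, no feed: mw(t) = mw(0) exp(-lambda t) with
        # lambda = km (pv_s - pv) m~_ai -- closed-form oracle
        params = CellParams()
        T, p, phi = 45.0, 101325.0, 0.2
        x = water_content_from_rh(phi, T, p)
        inputs = CellInputs(mdot_ai_net=0.02, T_ai_net=T, x_ai_net=x, T_aa=20.0, p=p)
        pv = phi * saturation_vapor_pressure(T)
        lam = params.km * (saturation_vapor_pressure(T) - pv) * 0.02
        y0 = CellState(mg=2.0, mw=1.0, xa=x, Ugw=(2 * params.cg + C.cw) * 25.0,
                       Uav=params.ma * humid_enthalpy(T, x)).as_array()

        def rhs(_t, y):
            return state_derivatives(CellState.from_array(y), inputs, params,
                                     Phase.DRYING)

        horizon = 3.0 / lam
        sol = solve_ivp(rhs, (0.0, horizon), y0, method="LSODA",
                        rtol=1e-9, atol=1e-12, t_eval=np.linspace(0, horizon, 40))
        exact = np.exp(-lam * sol.t)
        assert np.max(np.abs(sol.y[1] - exact) / exact) < 1e-4

    def test_nonnegative_states_preserved(self):
        # mw reaches zero asymptotically and xa stays nonnegative
        params = CellParams()
        T, p = 45.0, 101325.0
        x = water_content_from_rh(0.2, T, p)
        inputs = CellInputs(mdot_ai_net=0.02, T_ai_net=T, x_ai_net=x, T_aa=20.0, p=p)
        y0 = CellState(mg=2.0, mw=0.5, xa=x, Ugw=(2 * params.cg + 0.5 * C.cw) * 25.0,
                       Uav=params.ma * humid_enthalpy(T, x)).as_array()

        def rhs(_t, y):
            y = np.maximum(y, [0, 0, 0, -np.inf, -np.inf])
            return state_derivatives(CellState.from_array(y), inputs, params,
                                     Phase.DRYING)

        sol = solve_ivp(rhs, (0.0, 3000.0), y0, method="LSODA", rtol=1e-8, atol=1e-12)
        assert sol.y[1, -1] > -1e-9
        assert np.all(sol.y[2] >= 0)


class TestSensorTemperature:
    def test_unity_dc_gain(self):
        u = np.full(600, 37.0)
        y = sensor_temperature(u, u, ksep=0.1, tau_sensor=30.0, dt=1.0)
        assert y[-1] == pytest.approx(37.0, abs=1e-6)

    def test_first_order_step_response(self):
        # step applied at t=0 from filter state 0: 63.21 % at one time constant
        n = 121
        Tg = np.full(n, 10.0)
        y = sensor_temperature(Tg, Tg, ksep=0.0, tau_sensor=30.0, dt=1.0, y0=0.0)
        t = np.arange(n) * 1.0
        expected = 10.0 * (1.0 - np.exp(-t / 30.0))
        assert y[30] == pytest.approx(10.0 * 0.6321, rel=1e-2)
        assert np.allclose(y, expected, atol=0.12)

    def test_step_size_robust_discretization(self):
        rng = np.random.default_rng(0)
        u = np.repeat(rng.normal(30.0, 3.0, 40), 10)  # piecewise-constant signal
        fine = sensor_temperature(u, u, 0.1, 30.0, dt=0.5, y0=20.0)
        coarse = sensor_temperature(u[::10], u[::10], 0.1, 30.0, dt=5.0, y0=20.0)
        assert fine[::10] == pytest.approx(coarse, abs=1e-9)

    def test_ksep_zero_is_pure_granule_channel(self):
        Tg = np.linspace(20, 40, 50)
        Ta = np.full(50, 99.0)
        y = sensor_temperature(Tg, Ta, ksep=0.0, tau_sensor=0.0, dt=1.0)
        assert np.allclose(y, Tg)
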