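"""Dynamics of a single dryer cell.

One cell of the segmented fluid-bed dryer holds a shallow fluidized bed
of wet granules. Five states describe it:

    mg   dry granule mass                      [kg]
    mw   water mass contained in the granules  [kg]
    xa   water content of the cell air         [kg/kg dry air]
    Ugw  internal energy of granules + water   [J]
    Uav  internal energy of cell air + vapor   [J]

The dry-air holdup ma is a constant parameter (air density changes and
granule-displaced volume are neglected), so the dry-air balance forces
the outlet dry-air flow to equal the net inlet flow at every instant.

Heat and mass transfer use a deliberately simple phenomenological
closure: air-to-granule heat flow and wall loss are proportional to the
difference between a blended air temperature (1-k1) T~ai + k1 Ta and the
granule / ambient temperature; the evaporation rate is proportional to
the water holdup, the net inlet dry-air flow, and the vapor-pressure
deficit (pv_s - pv) evaluated at the NET INLET air condition (not the
cell air state). Falling-rate kinetics, particle-size effects and bed
hydrodynamics are out of scope.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import lfilter

from .psychro import (
    AirState,
    MoistAirConstants,
    humid_enthalpy,
    saturation_vapor_pressure,
    temperature_from_enthalpy,
)

log = logging.getLogger(__name__)

#: below this granule heat capacity [J/K] a cell counts as empty
EMPTY_HEAT_CAPACITY_EPS = 1e-9
#: below this total granule mass [kg] the LOD is undefined (masked)
EMPTY_MASS_EPS = 1e-9


class Phase(enum.Enum):
    """Discrete operating mode of one cell."""

    FILLING = "filling"
    DRYING = "drying"
    EMPTYING = "emptying"
    IDLE = "idle"


@dataclass(frozen=True)
class CellState:
    mg: float = 0.0
    mw: float = 0.0
    xa: float = 0.0
    Ugw: float = 0.0
    Uav: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.mg, self.mw, self.xa, self.Ugw, self.Uav])

    @classmethod
    def from_array(cls, y: np.ndarray) -> "CellState":
        return cls(*map(float, y))


@dataclass(frozen=True)
class CellParams:
    """Identifiable coefficients and fixed material constants of a cell.

    k1 blends net-inlet and cell air temperature in the heat-transfer
    driving force; kag and kloss are lumped heat-transfer coefficients
    [J/(K s)]; km is the drying-rate coefficient (fitted scalar; the
    closure multiplies it by mw [kg], a pressure deficit [Pa] and a dry
    air flow [kg/s] to yield kg/s); ma is the per-cell dry-air holdup
    [kg]; ksep blends air and granule temperature in the bottom-mounted
    PT100 sensor model; cg is the specific heat of the dry granules
    [J/(kg K)]; tau_sensor is the sensor first-order lag [s].
    """

    k1: float = 0.381
    kag: float = 3.22
    kloss: float = 0.353
    km: float = 1.77e-5
    ma: float = 0.197
    ksep: float = 0.1
    cg: float = 1300.0
    tau_sensor: float = 30.0

    def __post_init__(self) -> None:
        for name in ("kag", "kloss", "km", "ma", "cg", "tau_sensor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("k1", "ksep"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class CellInputs:
    """Boundary conditions of one cell at one instant.

    The net inlet air stream (tilde quantities) is the ideal mixture of
    the AHU split, pneumatic transport air and filter blowback air that
    actually enters the cell in the current phase.
    """

    mdot_ai_net: float  # net inlet dry-air mass flow [kg/s]
    T_ai_net: float     # net inlet air temperature [degC]
    x_ai_net: float     # net inlet water content [kg/kg]
    mdot_gi: float = 0.0  # dry granule inflow [kg/s]
    mdot_wi: float = 0.0  # water-in-granule inflow [kg/s]
    T_gi: float = 20.0    # granule inlet temperature [degC]
    T_aa: float = 20.0    # ambient temperature [degC]
    p: float = 101325.0   # total pressure [Pa]

    def __post_init__(self) -> None:
        if min(self.mdot_ai_net, self.mdot_gi, self.mdot_wi) < 0:
            raise ValueError("flows must be nonnegative")


def blended_air_temperature(T_ai_net: float, Ta: float, k1: float) -> float:
    """(1-k1) T~ai + k1 Ta — the effective air temperature seen by the bed."""
    return (1.0 - k1) * T_ai_net + k1 * Ta


def heat_flow_air_to_granules(T_ai_net: float, Ta: float, Tg: float, k1: float, kag: float) -> float:
    """Air-to-granule heat flow [W]; positive when the blended air is hotter."""
    return (blended_air_temperature(T_ai_net, Ta, k1) - Tg) * kag


def heat_loss(T_ai_net: float, Ta: float, T_aa: float, k1: float, kloss: float) -> float:
    """Heat flow through the cell wall to ambient [W]; wall heat capacity neglected."""
    return (blended_air_temperature(T_ai_net, Ta, k1) - T_aa) * kloss


def evaporation_rate(mw: float, inlet_air: AirState, mdot_ai_net: float, km: float) -> float:
    """Water evaporation rate [kg/s].

    km * mw * (pv_s - pv) * mdot_ai_net, with both vapor pressures taken
    at the net-inlet air condition. Floored at zero: condensation is not
    modeled, so supersaturated inlet air simply stops the drying.
    """
    if mw < 0:
        raise ValueError("water holdup must be nonnegative")
    driving = saturation_vapor_pressure(inlet_air.T) - inlet_air.vapor_pressure
    return km * mw * max(driving, 0.0) * mdot_ai_net


def granule_temperature(
    mg: float, mw: float, Ugw: float, cg: float, cw: float,
    fallback: float | None = None,
) -> float:
    """Granule bed temperature Tg = Ugw / (mg cg + mw cw) [degC].

    An empty cell has no defined granule temperature; the net inlet air
    temperature is reported as a placeholder (so downstream sensor
    filtering never sees NaN) when ``fallback`` is given, else an error.
    """
    C = mg * cg + mw * cw
    if C <= EMPTY_HEAT_CAPACITY_EPS:
        if fallback is None:
            raise ValueError("granule temperature undefined for an empty cell")
        return fallback
    return Ugw / C


def air_temperature(Uav: float, xa: float, ma: float, constants: MoistAirConstants) -> float:
    """Cell air temperature from the air+vapor internal energy [degC].

    Inverts Uav = ma (cp_a Ta + xa (cp_v Ta + dhe)).
    """
    if ma <= 0:
        raise ValueError("air holdup must be positive")
    return temperature_from_enthalpy(Uav / ma, xa, constants)


def lod(mw: float, mg: float) -> float:
    """Loss on drying, wet basis: 100 mw / (mg + mw) [%]. NaN when empty."""
    total = mg + mw
    if total <= EMPTY_MASS_EPS:
        return math.nan
    return 100.0 * mw / total


def empty_reset(state: CellState) -> CellState:
    """Pneumatic emptying: granules and their water leave within seconds.

    mg, mw and Ugw are set to zero; the cell air (xa, Uav) keeps
    evolving since air continues to flow. Idempotent.
    """
    return replace(state, mg=0.0, mw=0.0, Ugw=0.0)


def state_derivatives(
    state: CellState,
    inputs: CellInputs,
    params: CellParams,
    phase: Phase,
    constants: MoistAirConstants = MoistAirConstants(),
) -> np.ndarray:
    """Time derivatives (dmg, dmw, dxa, dUgw, dUav) of one cell.

    Valid outside the emptying discharge itself, which is handled as a
    discrete reset (:func:`empty_reset`) rather than via explicit
    discharge flows. The dry-air balance d ma/dt = 0 makes the outlet
    dry-air flow equal mdot_ai_net, which is substituted throughout.
    """
    if min(state.mg, state.mw, state.xa) < 0:
        raise ValueError("negative state passed to state_derivatives")
    c = constants
    Ta = air_temperature(state.Uav, state.xa, params.ma, c)
    empty = state.mg * params.cg + state.mw * c.cw <= EMPTY_HEAT_CAPACITY_EPS
    Tg = granule_temperature(state.mg, state.mw, state.Ugw, params.cg, c.cw,
                             fallback=inputs.T_ai_net)

    inlet = AirState(T=inputs.T_ai_net, x=inputs.x_ai_net, p=inputs.p)
    mdot_w = evaporation_rate(state.mw, inlet, inputs.mdot_ai_net, params.km)
    Q_ag = 0.0 if empty else heat_flow_air_to_granules(
        inputs.T_ai_net, Ta, Tg, params.k1, params.kag)
    Q_loss = heat_loss(inputs.T_ai_net, Ta, inputs.T_aa, params.k1, params.kloss)

    h_in = humid_enthalpy(inputs.T_ai_net, inputs.x_ai_net, c)
    h_a = humid_enthalpy(Ta, state.xa, c)

    dmg = inputs.mdot_gi
    dmw = inputs.mdot_wi - mdot_w
    dxa = (inputs.mdot_ai_net * (inputs.x_ai_net - state.xa) + mdot_w) / params.ma
    dUgw = (inputs.mdot_gi * params.cg * inputs.T_gi
            + inputs.mdot_wi * c.cw * inputs.T_gi
            - mdot_w * c.cw * Tg
            + Q_ag)
    dUav = (inputs.mdot_ai_net * (h_in - h_a)
            + mdot_w * c.cw * Tg
            - Q_loss
            - Q_ag)
    return np.array([dmg, dmw, dxa, dUgw, dUav])


def sensor_temperature(
    Tg_model: np.ndarray,
    T_ai_net: np.ndarray,
    ksep: float,
    tau_sensor: float,
    dt: float,
    y0: float | None = None,
) -> np.ndarray:
    """PT100 cell-sensor model: blend then first-order lag.

    The bottom-mounted sensor reads a convex combination
    ksep T~ai + (1-ksep) Tg of air and granule temperature, low-pass
    filtered with time constant tau_sensor. The lag is discretized
    exactly (zero-order hold): y[n] = a y[n-1] + (1-a) u[n] with
    a = exp(-dt/tau), so results are step-size robust.

    Parameters
    ----------
    Tg_model, T_ai_net : series on a uniform grid of spacing ``dt`` [s]
    y0 : initial filter state; defaults to the first blended sample
    """
    u = ksep * np.asarray(T_ai_net, float) + (1.0 - ksep) * np.asarray(Tg_model, float)
    if tau_sensor <= 0:
        return u.copy()
    a = math.exp(-dt / tau_sensor)
    # y[n] = a y[n-1] + (1-a) u[n-1]: sample n sees the input held over
    # the preceding step, the exact ZOH solution of the lag ODE
    zi = np.array([u[0] if y0 is None else y0])
    y, _ = lfilter([0.0, 1.0 - a], [1.0, -a], u, zi=zi)
    return y
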