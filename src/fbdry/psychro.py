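"""Humid-air property functions (psychrometrics).

All other modules build on these. Conventions: temperatures in degrees
Celsius, pressures in Pa, water content ("humidity ratio") x in kg water
vapor per kg dry air, relative humidity phi as a fraction. Air mass flows
are on a dry-air basis; the humid mass flow is the dry-air flow times
(1 + x).

Relative humidity values above 1 (100 %) are representable and are never
clamped: the simplified cell model deliberately lets individual cell air
become nominally supersaturated under some operating conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)

KELVIN_OFFSET = 273.15
#: molar-to-mass conversion factor M_w / M_a for vapor partial pressures
EPS_MOLAR_MASS = 0.622

# Validity window of the saturation-pressure polynomial [degC]
T_VALID_MIN = 0.0
T_VALID_MAX = 90.0


@dataclass(frozen=True)
class MoistAirConstants:
    """Physical constants of humid air.

    The identified dryer parameters were fitted jointly with whatever
    constant set the plant model used, so every value here is
    user-overridable; defaults are standard moist-air values.

    Attributes
    ----------
    Rv : specific gas constant of water vapor [J/(kg K)]
    cp_a : specific heat of dry air [J/(kg K)]
    cp_v : specific heat of water vapor [J/(kg K)]
    cw : specific heat of liquid water [J/(kg K)]
    dhe : specific evaporation enthalpy at the 0 degC reference [J/kg]
    """

    Rv: float = 461.5
    cp_a: float = 1005.0
    cp_v: float = 1860.0
    cw: float = 4186.0
    dhe: float = 2.501e6

    def __post_init__(self) -> None:
        for name in ("Rv", "cp_a", "cp_v", "cw", "dhe"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class AirState:
    """State of a humid-air stream: temperature, moisture, pressure.

    Exactly one of ``phi`` (relative humidity, fraction) or ``x`` (water
    content, kg/kg dry air) must be given; the other is derived lazily.
    """

    T: float
    p: float = 101325.0
    phi: float | None = None
    x: float | None = None

    def __post_init__(self) -> None:
        if self.p <= 0:
            raise ValueError("total pressure must be positive")
        if (self.phi is None) == (self.x is None):
            raise ValueError("specify exactly one of phi or x")
        if self.phi is not None and self.phi < 0:
            raise ValueError("relative humidity must be nonnegative")
        if self.x is not None and self.x < 0:
            raise ValueError("water content must be nonnegative")

    @property
    def water_content(self) -> float:
        if self.x is not None:
            return self.x
        return water_content_from_rh(self.phi, self.T, self.p)

    @property
    def rel_humidity(self) -> float:
        if self.phi is not None:
            return self.phi
        return rh_from_water_content(self.x, self.T, self.p)

    @property
    def vapor_pressure(self) -> float:
        if self.phi is not None:
            return self.phi * saturation_vapor_pressure(self.T)
        x = self.x
        return self.p * x / (EPS_MOLAR_MASS + x)


def saturation_vapor_pressure(T: float) -> float:
    """Saturation partial pressure of water vapor over liquid water [Pa].

    Quartic-exponent correlation, valid on [0, 90] degC; outside the
    window the polynomial is extrapolated with a logged warning rather
    than raising, since transient solver iterates may briefly leave it.
    """
    T = np.asarray(T, float) if np.ndim(T) else float(T)
    if np.any(np.asarray(T) < T_VALID_MIN) or np.any(np.asarray(T) > T_VALID_MAX):
        log.warning(
            "saturation_vapor_pressure extrapolated outside [%g, %g] degC",
            T_VALID_MIN, T_VALID_MAX,
        )
    return 611.0 * np.exp(
        -1.91275e-4
        + 7.258e-2 * T
        - 2.939e-4 * T**2
        + 9.841e-7 * T**3
        - 1.92e-9 * T**4
    )


def water_content_from_rh(phi: float, T: float, p: float) -> float:
    """Water content x [kg/kg dry air] from relative humidity.

    x = 0.622 pv / (p - pv) with pv = phi * pv_s(T).
    """
    if np.any(np.asarray(phi) < 0):
        raise ValueError("relative humidity must be nonnegative")
    pv = phi * saturation_vapor_pressure(T)
    if np.any(np.asarray(p) <= np.asarray(pv)):
        raise ValueError(
            "vapor pressure >= total pressure: water content is not representable"
        )
    return EPS_MOLAR_MASS * pv / (p - pv)


def rh_from_water_content(x: float, T: float, p: float) -> float:
    """Relative humidity (fraction) from water content x.

    Inverse of :func:`water_content_from_rh`. Values above 1 are
    returned as-is (supersaturated cell air is an accepted model state).
    """
    if np.any(np.asarray(x) < 0):
        raise ValueError("water content must be nonnegative")
    pv = p * x / (EPS_MOLAR_MASS + x)
    return pv / saturation_vapor_pressure(T)


def humid_enthalpy(T: float, x: float, constants: MoistAirConstants = MoistAirConstants()) -> float:
    """Specific enthalpy of humid air per kg DRY air [J/kg].

    h = cp_a T + x (dhe + cp_v T); reference state is dry air and liquid
    water at 0 degC. Linear in both T and x, which the outlet-mixing
    temperature reconstruction relies on.
    """
    return constants.cp_a * T + x * (constants.dhe + constants.cp_v * T)


def temperature_from_enthalpy(h: float, x: float, constants: MoistAirConstants = MoistAirConstants()) -> float:
    """Invert :func:`humid_enthalpy` for T at known water content x."""
    return (h - x * constants.dhe) / (constants.cp_a + x * constants.cp_v)


def dry_air_mass_flow(
    V_meas: float,
    T: float,
    phi: float,
    p: float,
    kV: float = 1.0,
    constants: MoistAirConstants = MoistAirConstants(),
) -> float:
    """Dry-air mass flow [kg/s] from a measured volume flow [m3/h].

    The measured volume flow is first corrected, V = kV * V_meas
    (the correction factor kV compensates flow-meter bias and is an
    identified parameter), then converted with the ideal-gas relation

        mdot = (p - pv) V / (0.622 Rv (T + 273.15)),

    which is algebraically identical to pv V / (x Rv T_K) for phi > 0
    but remains defined for perfectly dry air.
    """
    if V_meas < 0:
        raise ValueError("volume flow must be nonnegative")
    pv = phi * saturation_vapor_pressure(T)
    V = kV * V_meas / 3600.0
    return (p - pv) * V / (EPS_MOLAR_MASS * constants.Rv * (T + KELVIN_OFFSET))
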