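"""Six-cell dryer line: scheduler, air routing, and hybrid simulation.

The segmented dryer operates as a rotating calendar. Wet granules from
the granulator are blown into one cell at a time; every
``fill_switch_period`` (180 s) the transport line switches to the next
cell. After its fill window a cell dries for ``tdry`` seconds, is then
emptied pneumatically for 30 s (with a 10 s filter-blowback air pulse),
and idles until its next fill slot. The AHU air flow is split equally
between the six cells regardless of fill level.

The continuous dynamics (five states per cell, see :mod:`fbdry.cell`)
are integrated segment-wise between discrete events (fill switches,
drying ends, emptying edges, blowback edges, input setpoint steps) with
a stiff-capable adaptive solver; integration restarts at every event and
the emptying reset is applied exactly at the phase edge, so the hybrid
discontinuities are never smeared.

Five auxiliary cumulative states (water in/out, enthalpy in/out,
integrated wall loss) ride along with the cell states so that mass- and
energy-balance closure can be audited at integrator accuracy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import cell as _cell
from .cell import CellParams, Phase
from .psychro import (
    EPS_MOLAR_MASS,
    MoistAirConstants,
    dry_air_mass_flow,
    humid_enthalpy,
    rh_from_water_content,
    saturation_vapor_pressure,
    temperature_from_enthalpy,
    water_content_from_rh,
)

log = logging.getLogger(__name__)

N_STATES = 5        # per-cell: mg, mw, xa, Ugw, Uav
N_AUX = 5           # W_in, W_out, E_in, E_out, Q_loss (cumulative)

PHASE_CODES = {Phase.FILLING: 0, Phase.DRYING: 1, Phase.EMPTYING: 2, Phase.IDLE: 3}
PHASE_FROM_CODE = {v: k for k, v in PHASE_CODES.items()}

#: CSV column schema for input time series (units in the names)
INPUT_COLUMNS = (
    "time_s", "V_meas_m3h", "T_ai_C", "phi_ai", "T_aa_C", "phi_aa",
    "p_Pa", "mdot_p_kgh", "mdot_l_gmin", "wp_pct", "tdry_s",
)


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LineSchedule:
    """Timing of the fill/dry/empty rotation."""

    fill_switch_period: float = 180.0
    empty_duration: float = 30.0
    blowback_duration: float = 10.0
    n_cells: int = 6
    cell_order: tuple[int, ...] | None = None  # fill rotation; default 0..5

    def __post_init__(self) -> None:
        if self.blowback_duration > self.empty_duration:
            raise ValueError("blowback window must fit inside the emptying phase")
        order = self.cell_order
        if order is not None and sorted(order) != list(range(self.n_cells)):
            raise ValueError("cell_order must be a permutation of the cells")

    @property
    def order(self) -> tuple[int, ...]:
        return self.cell_order or tuple(range(self.n_cells))


@dataclass(frozen=True)
class LineParams:
    """Parameters of the whole line (per-cell params + air routing)."""

    cell: CellParams = field(default_factory=CellParams)
    kV: float = 0.807          # volume-flow correction factor [-]
    alpha_in_e: float = 1.0 / 35.0  # share of AHU inlet air leaving via emptying [-]
    alpha_f_e: float = 0.13    # share of blowback air leaving via emptying [-]
    Vdot_af: float = 20.0      # filter blowback volume flow [m3/h]
    mdot_ap: float = 0.0       # pneumatic transport dry-air flow [kg/s]
    T_gi: float | None = None  # granule inlet temperature [degC]; None -> ambient
    constants: MoistAirConstants = field(default_factory=MoistAirConstants)

    def __post_init__(self) -> None:
        for name in ("alpha_in_e", "alpha_f_e"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class SolverOptions:
    """Integrator and output-grid settings."""

    method: str = "LSODA"
    rtol: float = 1e-8
    atol: float = 1e-10
    dt_out: float = 1.0
    max_step: float = np.inf


# ---------------------------------------------------------------------------
# inputs
# ---------------------------------------------------------------------------

@dataclass
class LineInputs:
    """Measured/commanded process inputs as zero-order-hold step series.

    All arrays share the (monotone) time grid ``t`` [s from run start];
    a value holds from its timestamp until the next one. The horizon
    ends at ``t_end``.
    """

    t: np.ndarray            # [s]
    V_meas: np.ndarray       # [m3/h]
    T_ai: np.ndarray         # [degC]
    phi_ai: np.ndarray       # [-]
    T_aa: np.ndarray         # [degC]
    phi_aa: np.ndarray       # [-]
    p: np.ndarray            # [Pa]
    mdot_p: np.ndarray       # pre-blend feed [kg/h]
    mdot_l: np.ndarray       # liquid feed [g/min]
    wp: np.ndarray           # pre-blend LOD [%]
    tdry: np.ndarray         # drying time [s]
    t_end: float | None = None

    _FIELDS = ("V_meas", "T_ai", "phi_ai", "T_aa", "phi_aa", "p",
               "mdot_p", "mdot_l", "wp", "tdry")

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("input time grid must be strictly increasing")
        for name in self._FIELDS:
            arr = np.atleast_1d(np.asarray(getattr(self, name), float))
            if arr.size == 1:
                arr = np.full_like(self.t, arr[0])
            if arr.shape != self.t.shape:
                raise ValueError(f"input column {name} does not match the time grid")
            if np.any(arr < 0) and name != "T_aa" and name != "T_ai":
                raise ValueError(f"input column {name} must be nonnegative")
            setattr(self, name, arr)
        if self.t_end is None:
            self.t_end = float(self.t[-1])

    def at(self, time: float) -> dict[str, float]:
        """ZOH lookup of every input column at ``time``."""
        i = int(np.clip(np.searchsorted(self.t, time, side="right") - 1, 0, len(self.t) - 1))
        return {name: float(getattr(self, name)[i]) for name in self._FIELDS}

    def breakpoints(self) -> np.ndarray:
        """Times at which any input column changes value."""
        cols = np.column_stack([getattr(self, n) for n in self._FIELDS])
        changed = np.any(cols[1:] != cols[:-1], axis=1)
        return np.concatenate([self.t[:1], self.t[1:][changed]])

    def to_frame(self) -> pd.DataFrame:
        data = {"time_s": self.t, "V_meas_m3h": self.V_meas, "T_ai_C": self.T_ai,
                "phi_ai": self.phi_ai, "T_aa_C": self.T_aa, "phi_aa": self.phi_aa,
                "p_Pa": self.p, "mdot_p_kgh": self.mdot_p, "mdot_l_gmin": self.mdot_l,
                "wp_pct": self.wp, "tdry_s": self.tdry}
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, t_end: float | None = None) -> "LineInputs":
        missing = set(INPUT_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"input table is missing columns: {sorted(missing)}")
        return cls(
            t=df["time_s"].to_numpy(float),
            V_meas=df["V_meas_m3h"].to_numpy(float),
            T_ai=df["T_ai_C"].to_numpy(float),
            phi_ai=df["phi_ai"].to_numpy(float),
            T_aa=df["T_aa_C"].to_numpy(float),
            phi_aa=df["phi_aa"].to_numpy(float),
            p=df["p_Pa"].to_numpy(float),
            mdot_p=df["mdot_p_kgh"].to_numpy(float),
            mdot_l=df["mdot_l_gmin"].to_numpy(float),
            wp=df["wp_pct"].to_numpy(float),
            tdry=df["tdry_s"].to_numpy(float),
            t_end=t_end,
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, t_end: float | None = None) -> "LineInputs":
        return cls.from_frame(pd.read_csv(path), t_end=t_end)


# ---------------------------------------------------------------------------
# elementary line operations
# ---------------------------------------------------------------------------

def split_inlet(mdot_ai_t: float, n_cells: int = 6) -> float:
    """Equal split of the total AHU dry-air flow: each cell gets 1/6."""
    if mdot_ai_t < 0:
        raise ValueError("total inlet air flow must be nonnegative")
    return mdot_ai_t / n_cells


def granule_feed_streams(mdot_p: float, mdot_l: float, wp: float) -> tuple[float, float]:
    """Split the wet feed into dry-granule and water streams [kg/s].

    mdot_p is the pre-blend feed in kg/h (carrying wp % water, wet
    basis), mdot_l the granulation-liquid feed in g/min. Total wet mass
    is conserved: mdot_gi + mdot_wi equals the summed feeds in kg/s.
    """
    if not 0.0 <= wp < 100.0:
        raise ValueError("pre-blend LOD must lie in [0, 100) %")
    mp = mdot_p / 3600.0
    ml = mdot_l / 1000.0 / 60.0
    mdot_gi = mp * (1.0 - wp / 100.0)
    mdot_wi = mp * wp / 100.0 + ml
    return mdot_gi, mdot_wi


def emptying_air_flow(mdot_ai_t: float, mdot_af: float, params: LineParams,
                      phase: Phase = Phase.EMPTYING) -> float:
    """Dry-air flow leaving with the pneumatic emptying transport [kg/s].

    A fixed share of the AHU inlet flow plus a fixed share of the
    (instantaneous) blowback flow; zero outside the emptying phase.
    """
    if phase is not Phase.EMPTYING:
        return 0.0
    return params.alpha_in_e * mdot_ai_t + params.alpha_f_e * mdot_af


def mix_streams(flows, temperatures, contents,
                constants: MoistAirConstants = MoistAirConstants()) -> tuple[float, float, float]:
    """Ideal adiabatic mixing of dry-air streams.

    Returns (total dry-air flow, mixed temperature, mixed water
    content). Water content is the flow-weighted mean; the temperature
    solves the enthalpy balance h(T, x_mix) * m_tot = sum m_j h_j.
    """
    m = np.asarray(flows, float)
    T = np.asarray(temperatures, float)
    x = np.asarray(contents, float)
    m_tot = float(m.sum())
    if m_tot <= 0:
        raise ValueError("net inlet dry-air flow must be positive (configuration error)")
    x_mix = float((m * x).sum() / m_tot)
    h_mix = float((m * humid_enthalpy(T, x, constants)).sum() / m_tot)
    T_mix = temperature_from_enthalpy(h_mix, x_mix, constants)
    return m_tot, float(T_mix), x_mix


def net_inlet_mixing(
    phase: Phase,
    split_flow: float,
    split_T: float,
    split_x: float,
    transport: tuple[float, float, float] | None = None,
    blowback: tuple[float, float, float] | None = None,
    constants: MoistAirConstants = MoistAirConstants(),
) -> tuple[float, float, float]:
    """Net inlet air (m~_ai, T~_ai, x~_ai) of one cell in a given phase.

    The AHU split always enters; pneumatic transport air joins during
    filling and blowback air during the blowback pulse. Streams are
    given as (dry-air flow [kg/s], T [degC], x [kg/kg]).
    """
    flows, Ts, xs = [split_flow], [split_T], [split_x]
    if phase is Phase.FILLING and transport is not None and transport[0] > 0:
        flows.append(transport[0]); Ts.append(transport[1]); xs.append(transport[2])
    if phase is Phase.EMPTYING and blowback is not None and blowback[0] > 0:
        flows.append(blowback[0]); Ts.append(blowback[1]); xs.append(blowback[2])
    return mix_streams(flows, Ts, xs, constants)


def outlet_mixing(mdot_ao, x_ao, T_a, constants: MoistAirConstants = MoistAirConstants()):
    """Mix the six cell outlet streams into the plenum condition.

    Accepts arrays whose LAST axis indexes the cells, so a whole
    trajectory can be mixed at once. Returns (m_ao_t, x_ao_t, T_ao_t).
    The mixed temperature is the exact algebraic inversion of the
    enthalpy balance at the mixed water content.
    """
    m = np.asarray(mdot_ao, float)
    x = np.asarray(x_ao, float)
    T = np.asarray(T_a, float)
    m_tot = m.sum(axis=-1)
    if np.any(m_tot <= 0):
        raise ValueError("total outlet air flow must be positive")
    x_tot = (x * m).sum(axis=-1) / m_tot
    h_k = humid_enthalpy(T, x, constants)
    T_tot = ((m * h_k).sum(axis=-1) - x_tot * constants.dhe * m_tot) / (
        m_tot * (constants.cp_a + x_tot * constants.cp_v))
    return m_tot, x_tot, T_tot


# ---------------------------------------------------------------------------
# timeline (discrete phases)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Interval:
    t0: float
    t1: float
    phase: Phase


class Timeline:
    """Per-cell phase calendar over a simulation horizon.

    Built once from the schedule and the (piecewise-constant) tdry
    input: fill slot j covers [j P, (j+1) P) and belongs to cell
    order[j mod 6]; drying lasts tdry (sampled at fill end), then the
    30 s emptying with its blowback window, then idle.
    """

    def __init__(self, schedule: LineSchedule, inputs: LineInputs, t_end: float):
        self.schedule = schedule
        self.t_end = float(t_end)
        P = schedule.fill_switch_period
        n = schedule.n_cells
        order = schedule.order
        intervals: list[list[_Interval]] = [[] for _ in range(n)]
        self.empty_starts: list[tuple[float, int]] = []
        self.blowback_windows: list[tuple[float, float, int]] = []
        j = 0
        while j * P < self.t_end:
            k = order[j % n]
            t_fill0, t_fill1 = j * P, (j + 1) * P
            tdry = inputs.at(min(t_fill1, self.t_end) - 1e-9)["tdry"]
            if tdry <= 0:
                raise ValueError("tdry must be positive")
            t_dry1 = t_fill1 + tdry
            t_empty1 = t_dry1 + schedule.empty_duration
            if t_empty1 > t_fill0 + n * P:
                warnings.warn(
                    f"cell {k}: drying+emptying ({t_empty1 - t_fill1:.0f} s) does not fit "
                    f"the rotation ({n * P - P:.0f} s available); cell still busy when refilled",
                    stacklevel=2,
                )
            intervals[k].append(_Interval(t_fill0, t_fill1, Phase.FILLING))
            intervals[k].append(_Interval(t_fill1, t_dry1, Phase.DRYING))
            intervals[k].append(_Interval(t_dry1, t_empty1, Phase.EMPTYING))
            self.empty_starts.append((t_dry1, k))
            self.blowback_windows.append((t_dry1, t_dry1 + schedule.blowback_duration, k))
            j += 1
        self._intervals = intervals
        ev = {0.0, self.t_end}
        for cell_iv in intervals:
            for iv in cell_iv:
                ev.update((iv.t0, iv.t1))
        for (b0, b1, _k) in self.blowback_windows:
            ev.update((b0, b1))
        self.events = np.array(sorted(t for t in ev if 0.0 <= t <= self.t_end))

    def phase_of(self, k: int, t: float) -> Phase:
        for iv in self._intervals[k]:
            if iv.t0 <= t < iv.t1:
                return iv.phase
        return Phase.IDLE

    def phases_at(self, t: float) -> list[Phase]:
        return [self.phase_of(k, t) for k in range(self.schedule.n_cells)]

    def blowback_active(self, k: int, t: float) -> bool:
        return any(b0 <= t < b1 and bk == k for (b0, b1, bk) in self.blowback_windows)

    def cells_entering_empty(self, t: float, tol: float = 1e-9) -> list[int]:
        return [k for (te, k) in self.empty_starts if abs(te - t) <= tol]


def step_schedule(t: float, schedule: LineSchedule, inputs: LineInputs,
                  t_start: float = 0.0) -> list[Phase]:
    """Per-cell phase at time ``t`` (convenience wrapper over Timeline)."""
    tl = Timeline(schedule, inputs, t_end=max(t + 1.0, inputs.t_end))
    return tl.phases_at(t - t_start)


# ---------------------------------------------------------------------------
# trajectory container
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Time-indexed record of the full line simulation.

    Per-cell arrays have shape (n_times, n_cells); LOD is NaN-masked
    where a cell is empty. The ``aux`` columns are the cumulative
    water/enthalpy flow integrals used by :meth:`water_balance` and
    :meth:`energy_balance`; ``discarded_water`` / ``discarded_energy``
    are cumulative step functions recording what the emptying resets
    removed from the balance envelope.
    """

    t: np.ndarray
    mg: np.ndarray
    mw: np.ndarray
    xa: np.ndarray
    Ugw: np.ndarray
    Uav: np.ndarray
    Tg: np.ndarray
    Ta: np.ndarray
    T_sensed: np.ndarray
    lod: np.ndarray
    phase: np.ndarray            # int codes, (n_times, n_cells)
    mdot_ai_net: np.ndarray      # (n_times, n_cells)
    T_ai_net: np.ndarray
    x_ai_net: np.ndarray
    mdot_ae: np.ndarray
    mdot_ai_t: np.ndarray        # (n_times,)
    mdot_ao_t: np.ndarray
    x_ao_t: np.ndarray
    T_ao_t: np.ndarray
    phi_ao_t: np.ndarray
    aux: np.ndarray              # (n_times, N_AUX)
    discarded_water: np.ndarray
    discarded_energy: np.ndarray
    params: LineParams | None = None

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def phase_mask(self, k: int, phase: Phase) -> np.ndarray:
        return self.phase[:, k] == PHASE_CODES[phase]

    def stored_water(self) -> np.ndarray:
        """Water held in granules and cell air at each instant [kg]."""
        ma = self.params.cell.ma if self.params else CellParams().ma
        return self.mw.sum(axis=1) + (ma * self.xa).sum(axis=1)

    def water_balance(self) -> dict[str, float]:
        """Global water balance over the trajectory [kg].

        in (feed + inlet air) = out (all outlet air) + discarded at
        emptying + change in storage + residual; the relative residual
        is normalized by total water input.
        """
        W_in = self.aux[-1, 0] - self.aux[0, 0]
        W_out = self.aux[-1, 1] - self.aux[0, 1]
        d_store = self.stored_water()[-1] - self.stored_water()[0]
        d_disc = self.discarded_water[-1] - self.discarded_water[0]
        residual = W_in - W_out - d_disc - d_store
        return {"in": float(W_in), "out": float(W_out), "discarded": float(d_disc),
                "stored": float(d_store), "residual": float(residual),
                "relative_residual": float(residual / W_in) if W_in else 0.0}

    def energy_balance(self) -> dict[str, float]:
        """Global energy balance over the trajectory [J], like water_balance."""
        E_in = self.aux[-1, 2] - self.aux[0, 2]
        E_out = self.aux[-1, 3] - self.aux[0, 3]
        Q_loss = self.aux[-1, 4] - self.aux[0, 4]
        store = (self.Ugw + self.Uav).sum(axis=1)
        d_store = store[-1] - store[0]
        d_disc = self.discarded_energy[-1] - self.discarded_energy[0]
        residual = E_in - E_out - Q_loss - d_disc - d_store
        scale = max(abs(E_in), abs(E_out), 1.0)
        return {"in": float(E_in), "out": float(E_out), "wall_loss": float(Q_loss),
                "discarded": float(d_disc), "stored": float(d_store),
                "residual": float(residual), "relative_residual": float(residual / scale)}

    def to_frame(self) -> pd.DataFrame:
        n_cells = self.mg.shape[1]
        data: dict[str, np.ndarray] = {"time_s": self.t}
        for name, arr in (("lod_pct", self.lod), ("Tg_C", self.Tg), ("Ta_C", self.Ta),
                          ("T_sensed_C", self.T_sensed), ("mg_kg", self.mg),
                          ("mw_kg", self.mw), ("xa_kgkg", self.xa)):
            for k in range(n_cells):
                data[f"{name}_cell{k + 1}"] = arr[:, k]
        data["mdot_ai_t_kgs"] = self.mdot_ai_t
        data["T_ao_t_C"] = self.T_ao_t
        data["x_ao_t_kgkg"] = self.x_ao_t
        data["phi_ao_t"] = self.phi_ao_t
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

@dataclass
class _SegmentContext:
    """Everything constant within one inter-event segment."""

    mdot_ai_t: float
    mdot_ai_net: np.ndarray   # (6,)
    T_ai_net: np.ndarray
    x_ai_net: np.ndarray
    h_ai_net: np.ndarray
    driving: np.ndarray       # max(pv_s - pv, 0) at the net inlet condition [Pa]
    mdot_gi: np.ndarray
    mdot_wi: np.ndarray
    T_gi: float
    T_aa: float
    p: float
    mdot_ae: np.ndarray
    phases: list[Phase]


def _segment_context(t0: float, inputs: LineInputs, params: LineParams,
                     timeline: Timeline) -> _SegmentContext:
    u = inputs.at(t0)
    c = params.constants
    n = timeline.schedule.n_cells
    mdot_ai_t = dry_air_mass_flow(u["V_meas"], u["T_ai"], u["phi_ai"], u["p"],
                                  kV=params.kV, constants=c)
    split = split_inlet(mdot_ai_t, n)
    x_ai = water_content_from_rh(u["phi_ai"], u["T_ai"], u["p"])
    x_aa = water_content_from_rh(u["phi_aa"], u["T_aa"], u["p"])
    T_gi = params.T_gi if params.T_gi is not None else u["T_aa"]
    gi, wi = granule_feed_streams(u["mdot_p"], u["mdot_l"], u["wp"])

    phases = timeline.phases_at(t0)
    m_net = np.empty(n); T_net = np.empty(n); x_net = np.empty(n)
    mdot_gi = np.zeros(n); mdot_wi = np.zeros(n); mdot_ae = np.zeros(n)
    for k in range(n):
        blow = None
        if phases[k] is Phase.EMPTYING and timeline.blowback_active(k, t0):
            mdot_af = dry_air_mass_flow(params.Vdot_af, u["T_aa"], u["phi_aa"],
                                        u["p"], kV=1.0, constants=c)
            blow = (mdot_af, u["T_aa"], x_aa)
        transport = (params.mdot_ap, u["T_aa"], x_aa) if phases[k] is Phase.FILLING else None
        m_net[k], T_net[k], x_net[k] = net_inlet_mixing(
            phases[k], split, u["T_ai"], x_ai, transport=transport,
            blowback=blow, constants=c)
        if phases[k] is Phase.FILLING:
            mdot_gi[k], mdot_wi[k] = gi, wi
        if phases[k] is Phase.EMPTYING:
            mdot_ae[k] = emptying_air_flow(mdot_ai_t, blow[0] if blow else 0.0, params)
    pv_net = u["p"] * x_net / (EPS_MOLAR_MASS + x_net)
    driving = np.maximum(saturation_vapor_pressure(T_net) - pv_net, 0.0)
    h_net = humid_enthalpy(T_net, x_net, c)
    return _SegmentContext(mdot_ai_t, m_net, T_net, x_net, h_net, driving,
                           mdot_gi, mdot_wi, T_gi, u["T_aa"], u["p"], mdot_ae, phases)


def _make_rhs(ctx: _SegmentContext, params: LineParams, n_cells: int):
    cp = params.cell
    c = params.constants
    cg, cw, cpa, cpv, dhe = cp.cg, c.cw, c.cp_a, c.cp_v, c.dhe

    def rhs(_t, y):
        s = y[: n_cells * N_STATES].reshape(n_cells, N_STATES)
        mg, mw, xa = s[:, 0], s[:, 1], s[:, 2]
        Ugw, Uav = s[:, 3], s[:, 4]
        mw_pos = np.maximum(mw, 0.0)
        Ta = (Uav / cp.ma - xa * dhe) / (cpa + xa * cpv)
        C = mg * cg + mw_pos * cw
        empty = C <= _cell.EMPTY_HEAT_CAPACITY_EPS
        Tg = np.where(empty, ctx.T_ai_net, Ugw / np.where(empty, 1.0, C))
        T_blend = (1.0 - cp.k1) * ctx.T_ai_net + cp.k1 * Ta
        mdot_w = cp.km * mw_pos * ctx.driving * ctx.mdot_ai_net
        Q_ag = np.where(empty, 0.0, (T_blend - Tg) * cp.kag)
        Q_loss = (T_blend - ctx.T_aa) * cp.kloss
        h_a = cpa * Ta + xa * (dhe + cpv * Ta)

        dy = np.empty_like(y)
        d = dy[: n_cells * N_STATES].reshape(n_cells, N_STATES)
        d[:, 0] = ctx.mdot_gi
        d[:, 1] = ctx.mdot_wi - mdot_w
        d[:, 2] = (ctx.mdot_ai_net * (ctx.x_ai_net - xa) + mdot_w) / cp.ma
        d[:, 3] = (ctx.mdot_gi * cg * ctx.T_gi + ctx.mdot_wi * cw * ctx.T_gi
                   - mdot_w * cw * Tg + Q_ag)
        d[:, 4] = (ctx.mdot_ai_net * (ctx.h_ai_net - h_a)
                   + mdot_w * cw * Tg - Q_loss - Q_ag)
        aux = dy[n_cells * N_STATES:]
        aux[0] = ctx.mdot_wi.sum() + float((ctx.mdot_ai_net * ctx.x_ai_net).sum())
        aux[1] = float((ctx.mdot_ai_net * xa).sum())
        aux[2] = float((ctx.mdot_gi * cg * ctx.T_gi + ctx.mdot_wi * cw * ctx.T_gi).sum()
                       + (ctx.mdot_ai_net * ctx.h_ai_net).sum())
        aux[3] = float((ctx.mdot_ai_net * h_a).sum())
        aux[4] = float(Q_loss.sum())
        return dy

    return rhs


def initial_state(inputs: LineInputs, params: LineParams,
                  n_cells: int = 6) -> np.ndarray:
    """Cold-start state: cells empty, cell air at the AHU inlet condition."""
    u = inputs.at(0.0)
    c = params.constants
    x0 = water_content_from_rh(u["phi_ai"], u["T_ai"], u["p"])
    Uav0 = params.cell.ma * humid_enthalpy(u["T_ai"], x0, c)
    y = np.zeros(n_cells * N_STATES + N_AUX)
    s = y[: n_cells * N_STATES].reshape(n_cells, N_STATES)
    s[:, 2] = x0
    s[:, 4] = Uav0
    return y


def simulate_line(
    inputs: LineInputs,
    params: LineParams | None = None,
    schedule: LineSchedule | None = None,
    solver: SolverOptions | None = None,
    t_end: float | None = None,
    y0: np.ndarray | None = None,
) -> Trajectory:
    """Simulate the six-cell line over [0, t_end].

    Deterministic given inputs and options. Integration is restarted at
    every discrete event (phase switches, blowback edges, input steps);
    the emptying reset (mg = mw = 0, Ugw = 0) is applied exactly at the
    phase edge and the discarded water/energy is logged so the global
    balances still close.
    """
    params = params or LineParams()
    schedule = schedule or LineSchedule()
    solver = solver or SolverOptions()
    t_end = float(t_end if t_end is not None else inputs.t_end)
    n = schedule.n_cells

    timeline = Timeline(schedule, inputs, t_end)
    edges = np.unique(np.concatenate([
        timeline.events,
        inputs.breakpoints(),
        [0.0, t_end],
    ]))
    edges = edges[(edges >= 0.0) & (edges <= t_end)]

    grid = np.arange(0.0, t_end + 0.5 * solver.dt_out, solver.dt_out)
    y = (initial_state(inputs, params, n) if y0 is None else np.asarray(y0, float).copy())

    n_t = len(grid)
    states = np.empty((n_t, n * N_STATES + N_AUX))
    ctx_idx = np.empty(n_t, dtype=int)
    contexts: list[_SegmentContext] = []
    disc_w_grid = np.empty(n_t)
    disc_e_grid = np.empty(n_t)
    disc_w = disc_e = 0.0

    pos = 0
    for i in range(len(edges) - 1):
        t0, t1 = float(edges[i]), float(edges[i + 1])
        # discrete transition handling at the segment start
        for k in timeline.cells_entering_empty(t0):
            sk = y[k * N_STATES: (k + 1) * N_STATES]
            disc_w += sk[1]
            disc_e += sk[3]
            sk[0] = sk[1] = sk[3] = 0.0
            log.info("t=%.1f s: cell %d emptied (reset applied)", t0, k + 1)
        ctx = _segment_context(t0 + 1e-9, inputs, params, timeline)
        contexts.append(ctx)
        rhs = _make_rhs(ctx, params, n)
        t_eval = grid[(grid >= t0 - 1e-9) & (grid < t1 - 1e-9)]
        sol = solve_ivp(rhs, (t0, t1), y, method=solver.method,
                        rtol=solver.rtol, atol=solver.atol,
                        max_step=solver.max_step,
                        t_eval=np.concatenate([t_eval, [t1]]))
        if not sol.success:
            raise RuntimeError(
                f"integration failed in segment [{t0:.1f}, {t1:.1f}] s "
                f"(phases {[p.value for p in ctx.phases]}): {sol.message}")
        m = len(t_eval)
        states[pos: pos + m] = sol.y[:, :m].T
        ctx_idx[pos: pos + m] = len(contexts) - 1
        disc_w_grid[pos: pos + m] = disc_w
        disc_e_grid[pos: pos + m] = disc_e
        pos += m
        y = sol.y[:, -1].copy()
    # final grid point coincides with t_end
    if pos < n_t:
        states[pos:] = y
        ctx_idx[pos:] = len(contexts) - 1
        disc_w_grid[pos:] = disc_w
        disc_e_grid[pos:] = disc_e

    return _assemble(grid, states, ctx_idx, contexts, disc_w_grid, disc_e_grid,
                     timeline, params, solver)


def _assemble(grid, states, ctx_idx, contexts, disc_w, disc_e,
              timeline: Timeline, params: LineParams, solver: SolverOptions) -> Trajectory:
    n = timeline.schedule.n_cells
    c = params.constants
    cp = params.cell
    s = states[:, : n * N_STATES].reshape(len(grid), n, N_STATES)
    mg, mw, xa = s[..., 0], np.maximum(s[..., 1], 0.0), s[..., 2]
    Ugw, Uav = s[..., 3], s[..., 4]

    m_net = np.array([contexts[i].mdot_ai_net for i in ctx_idx])
    T_net = np.array([contexts[i].T_ai_net for i in ctx_idx])
    x_net = np.array([contexts[i].x_ai_net for i in ctx_idx])
    mdot_ae = np.array([contexts[i].mdot_ae for i in ctx_idx])
    mdot_ai_t = np.array([contexts[i].mdot_ai_t for i in ctx_idx])
    p_tot = np.array([contexts[i].p for i in ctx_idx])
    T_aa0 = contexts[0].T_aa
    phase = np.array([[PHASE_CODES[ph] for ph in contexts[i].phases] for i in ctx_idx])

    Ta = (Uav / cp.ma - xa * c.dhe) / (c.cp_a + xa * c.cp_v)
    C = mg * cp.cg + mw * c.cw
    empty = C <= _cell.EMPTY_HEAT_CAPACITY_EPS
    Tg = np.where(empty, T_net, Ugw / np.where(empty, 1.0, C))
    total = mg + mw
    lod = np.where(total > _cell.EMPTY_MASS_EPS, 100.0 * mw / np.where(total > 0, total, 1.0), np.nan)

    mdot_ao = m_net - mdot_ae
    mdot_ao_t, x_ao_t, T_ao_t = outlet_mixing(mdot_ao, xa, Ta, c)
    phi_ao_t = rh_from_water_content(x_ao_t, T_ao_t, p_tot)
    if np.any(phi_ao_t > 1.0):
        log.info("mixed outlet air exceeds 100%% RH at %d samples", int((phi_ao_t > 1).sum()))

    T_sensed = np.empty_like(Tg)
    for k in range(n):
        T_sensed[:, k] = _cell.sensor_temperature(
            Tg[:, k], T_net[:, k], cp.ksep, cp.tau_sensor, solver.dt_out, y0=T_aa0)

    return Trajectory(
        t=grid, mg=mg, mw=mw, xa=xa, Ugw=Ugw, Uav=Uav, Tg=Tg, Ta=Ta,
        T_sensed=T_sensed, lod=lod, phase=phase,
        mdot_ai_net=m_net, T_ai_net=T_net, x_ai_net=x_net, mdot_ae=mdot_ae,
        mdot_ai_t=mdot_ai_t, mdot_ao_t=mdot_ao_t, x_ao_t=x_ao_t, T_ao_t=T_ao_t,
        phi_ao_t=phi_ao_t, aux=states[:, n * N_STATES:],
        discarded_water=disc_w, discarded_energy=disc_e, params=params,
    )
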