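"""Synthetic process-data generation.

No plant data stream ships with this package, so every downstream
module is exercised against data produced here: stepwise experiment
schedules (the identification and validation runs each held the feed
rates fixed at 20 kg/h pre-blend + 40 g/min liquid and stepped the
inlet air temperature 40-50 degC, the volume flow 260-400 m3/h and the
drying time 480-680 s), plus noisy "measured" outputs generated by a
ground-truth simulation with sensor models applied.

What the generator emulates: the setpoint step structure of the plant
experiments, the PT100 blend+lag sensing, the probe's affine raw/LOD
mapping, and additive Gaussian instrument noise. What it does not:
sensor fouling (material sticking to the probes), cell-to-cell air
maldistribution, and startup transients of the upstream granulator.

Ambient conditions, pre-blend LOD and granule inlet temperature of the
plant runs are unreported; the defaults here (20 degC / 40 % RH /
101325 Pa ambient, wp = 2 %) are declared synthetic choices and are
config-overridable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .identify import IdentDataset, apply_params, extract_params, minmax_identify
from .line import LineInputs, LineParams, LineSchedule, SolverOptions, simulate_line
from .softsensor import CalibrationCurve

DEFAULT_AMBIENT = {"T_aa": 20.0, "phi_aa": 0.40, "p": 101325.0}
DEFAULT_WP = 2.0  # pre-blend LOD [%]


@dataclass(frozen=True)
class ExperimentStep:
    """One constant-setpoint interval of an experiment schedule."""

    t0: float          # [s]
    t1: float          # [s]
    mdot_p: float      # pre-blend feed [kg/h]
    mdot_l: float      # liquid feed [g/min]
    T_ai: float        # inlet air temperature [degC]
    V_meas: float      # measured inlet volume flow [m3/h]
    tdry: float        # drying time [s]


def _steps_from_clock(rows, day_start: str) -> tuple[ExperimentStep, ...]:
    """Rows of (hh:mm-hh:mm, mdot_p, mdot_l, T_ai, V, tdry) to seconds from run start."""
    def sec(hhmm: str) -> float:
        h, m = hhmm.split(":")
        return int(h) * 3600.0 + int(m) * 60.0

    t_ref = sec(day_start)
    steps = []
    for span, mp, ml, T, V, td in rows:
        a, b = span.split("-")
        steps.append(ExperimentStep(sec(a) - t_ref, sec(b) - t_ref, mp, ml, T, V, td))
    return tuple(steps)


# The identification-run schedule: 174 min, six setpoint intervals;
# inlet temperature drops 50->45 degC, volume flow steps 300->400 m3/h,
# drying time alternates 680/580/480 s.
IDENT_RUN_STEPS = _steps_from_clock([
    ("10:02-10:20", 20, 40, 50, 300, 680),
    ("10:20-10:28", 20, 40, 50, 300, 580),
    ("10:28-11:00", 20, 40, 45, 300, 580),
    ("11:00-11:39", 20, 40, 45, 300, 480),
    ("11:39-12:33", 20, 40, 45, 400, 580),
    ("12:33-12:56", 20, 40, 45, 400, 480),
], day_start="10:02")

# The validation-run schedule: 194 min at 40 degC inlet air.
VALIDATION_RUN_STEPS = _steps_from_clock([
    ("11:06-11:28", 20, 40, 40, 260, 680),
    ("11:28-12:06", 20, 40, 40, 300, 680),
    ("12:06-12:46", 20, 40, 40, 300, 580),
    ("12:46-13:40", 20, 40, 40, 400, 680),
    ("13:40-14:20", 20, 40, 40, 400, 580),
], day_start="11:06")

# Reduced 45-min identification scenario: three 15-min steps keeping
# the informative manipulations (tdry change, 300->400 m3/h flow step)
# at desk-scale runtime.
IDENT_RUN_SHORT_STEPS = (
    ExperimentStep(0.0, 900.0, 20, 40, 45, 300, 580),
    ExperimentStep(900.0, 1800.0, 20, 40, 45, 300, 480),
    ExperimentStep(1800.0, 2700.0, 20, 40, 45, 400, 580),
)

SCENARIOS = {
    "ident": IDENT_RUN_STEPS,
    "validation": VALIDATION_RUN_STEPS,
    "ident_short": IDENT_RUN_SHORT_STEPS,
}


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian measurement noise, per channel, in channel units.

    Defaults are plausible instrument scales (temperature 0.2 degC, RH
    0.5 % absolute -> outlet water content noise derived from it, probe
    LOD 0.15 %), declared as artifact choices. ``sensor_filter``
    toggles the 30 s PT100 lag in the generated cell temperatures.
    """

    sd_T: float = 0.2        # [degC] outlet + cell temperatures
    sd_x: float = 5e-5       # [kg/kg] outlet water content (~0.5 % RH at 30 degC)
    sd_lod: float = 0.15     # [%] probe LOD (on the calibrated scale)
    sensor_filter: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sd_T, self.sd_x, self.sd_lod) < 0:
            raise ValueError("noise standard deviations must be nonnegative")


NOISELESS = NoiseSpec(sd_T=0.0, sd_x=0.0, sd_lod=0.0)


def build_inputs(
    steps=IDENT_RUN_STEPS,
    ambient: dict | None = None,
    wp: float = DEFAULT_WP,
    dt: float = 1.0,
) -> LineInputs:
    """Zero-order-hold input series from an experiment step schedule."""
    steps = tuple(steps)
    for a, b in zip(steps, steps[1:]):
        if abs(a.t1 - b.t0) > 1e-9:
            raise ValueError(f"gap between steps at t={a.t1:.0f} s")
    amb = {**DEFAULT_AMBIENT, **(ambient or {})}
    t = np.arange(steps[0].t0, steps[-1].t1, dt)
    idx = np.searchsorted([s.t0 for s in steps], t, side="right") - 1
    col = lambda name: np.array([getattr(steps[i], name) for i in idx])
    T_ai = col("T_ai")
    return LineInputs(
        t=t,
        V_meas=col("V_meas"), T_ai=T_ai,
        phi_ai=_inlet_rh(amb, T_ai),
        T_aa=np.full_like(t, amb["T_aa"]), phi_aa=np.full_like(t, amb["phi_aa"]),
        p=np.full_like(t, amb["p"]),
        mdot_p=col("mdot_p"), mdot_l=col("mdot_l"),
        wp=np.full_like(t, wp), tdry=col("tdry"),
        t_end=float(steps[-1].t1),
    )


def _inlet_rh(amb: dict, T_ai: np.ndarray) -> np.ndarray:
    """AHU inlet relative humidity consistent with the ambient moisture.

    The AHU heats ambient air without adding or removing water, so the
    inlet water content equals the ambient one and the inlet RH follows
    from it at the commanded inlet temperature.
    """
    from .psychro import rh_from_water_content, water_content_from_rh

    x = water_content_from_rh(amb["phi_aa"], amb["T_aa"], amb["p"])
    return rh_from_water_content(np.full_like(np.asarray(T_ai, float), x), T_ai, amb["p"])


def generate_measurements(
    inputs: LineInputs,
    true_params: LineParams | None = None,
    schedule: LineSchedule | None = None,
    noise: NoiseSpec = NOISELESS,
    solver: SolverOptions | None = None,
    calibration: CalibrationCurve = CalibrationCurve(),
    t_start: float = 0.0,
) -> IdentDataset:
    """Simulate the ground truth and emit a noisy measured dataset.

    Sensor models applied to the truth: the ksep air/granule blend plus
    30 s lag for the six cell temperatures (already part of the
    simulated trajectory; can be bypassed via ``noise.sensor_filter``),
    and the probe calibration round-trip for the cell-5 LOD — the true
    LOD is mapped to a raw reading through the inverse affine curve,
    noise is added on the raw scale, and the reading is re-calibrated
    on ingest, exactly as plant LOD data are treated.

    Deterministic for a fixed seed.
    """
    true_params = true_params or LineParams()
    solver = solver or SolverOptions()
    traj = simulate_line(inputs, params=true_params, schedule=schedule, solver=solver)
    rng = np.random.default_rng(noise.seed)
    n_t, n_cells = traj.Tg.shape

    if noise.sensor_filter:
        Tg_meas = traj.T_sensed.copy()
    else:
        cp = true_params.cell
        Tg_meas = cp.ksep * traj.T_ai_net + (1 - cp.ksep) * traj.Tg
    Tg_meas = Tg_meas + rng.normal(0.0, noise.sd_T, Tg_meas.shape) if noise.sd_T else Tg_meas

    T_ao = traj.T_ao_t + (rng.normal(0.0, noise.sd_T, n_t) if noise.sd_T else 0.0)
    x_ao = traj.x_ao_t + (rng.normal(0.0, noise.sd_x, n_t) if noise.sd_x else 0.0)

    lod5_true = traj.lod[:, 4]
    mask = np.isfinite(lod5_true) & (traj.phase[:, 4] == 1)  # drying validity window
    raw = calibration.inverse(np.nan_to_num(lod5_true, nan=0.0))
    if noise.sd_lod:
        raw = raw + rng.normal(0.0, noise.sd_lod / calibration.slope, n_t)
    lod5_meas = np.where(mask, calibration(raw), np.nan)

    return IdentDataset(
        inputs=inputs, t=traj.t, T_ao_t=T_ao, x_ao_t=x_ao, Tg=Tg_meas,
        lod5=lod5_meas, lod5_mask=mask, t_start=t_start, t_end=float(traj.t[-1]),
    )


@dataclass
class RecoveryReport:
    """True vs recovered parameters of one identification experiment."""

    true_values: dict[str, float]
    recovered: dict[str, float]
    relative_errors: dict[str, float]
    max_F: float
    n_evals: int
    seed: int
    scenario: str
    wp: float
    noise: NoiseSpec

    def to_json(self, path=None) -> str:
        payload = {
            "scenario": self.scenario, "seed": self.seed, "wp_pct": self.wp,
            "noise": asdict(self.noise), "true": self.true_values,
            "recovered": self.recovered, "relative_errors": self.relative_errors,
            "max_F": self.max_F, "n_evals": self.n_evals,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def recovery_experiment(
    seed: int = 0,
    scenario: str = "ident_short",
    noise: NoiseSpec | None = None,
    true_params: LineParams | None = None,
    init_factor: float = 2.0,
    dt_out: float = 5.0,
    maxiter: int = 150,
    lsq_nfev: int = 40,
) -> RecoveryReport:
    """End-to-end parameter-recovery harness.

    Builds the scenario inputs, generates (optionally noisy) synthetic
    measurements at the ground-truth parameters, then runs the min-max
    identification from an initial guess with every fitted coordinate
    multiplied by ``init_factor``, and reports the relative errors.

    The identification solver runs at a relaxed tolerance (rtol 1e-6,
    5 s output grid) to keep the several-hundred simulations of the
    Nelder-Mead search at desk scale.
    """
    noise = noise if noise is not None else replace(NOISELESS, seed=seed)
    true_params = true_params or LineParams()
    steps = SCENARIOS[scenario] if isinstance(scenario, str) else scenario
    inputs = build_inputs(steps)

    gen_solver = SolverOptions(rtol=1e-8, atol=1e-10, dt_out=dt_out)
    dataset = generate_measurements(inputs, true_params=true_params, noise=noise,
                                    solver=gen_solver)

    truth = extract_params(true_params)
    init_values = {k: min(v * init_factor, 0.999 * _upper(k)) for k, v in truth.items()}
    init = apply_params(true_params, init_values)

    ident_solver = SolverOptions(method="RK45", rtol=1e-6, atol=1e-9, dt_out=dt_out)
    result = minmax_identify(dataset, initial=init, solver=ident_solver,
                             maxiter=maxiter, lsq_nfev=lsq_nfev)
    rel = {k: abs(result.values[k] - truth[k]) / abs(truth[k]) for k in truth}
    return RecoveryReport(
        true_values=truth, recovered=result.values, relative_errors=rel,
        max_F=result.max_F, n_evals=result.n_evals, seed=seed,
        scenario=scenario if isinstance(scenario, str) else "custom",
        wp=float(inputs.wp[0]), noise=noise,
    )


def _upper(name: str) -> float:
    from .identify import _LOGIT_PARAMS

    return _LOGIT_PARAMS.get(name, np.inf)
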