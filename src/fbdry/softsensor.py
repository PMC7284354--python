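"""Trivial observer: the line model run in parallel with the plant.

A trivial observer is a one-to-one copy of the process model driven by
the measured plant inputs (inlet air temperature, humidity, volume
flow, granule feed properties) with no output-feedback correction. Its
per-cell LOD prediction stands in for the NIR probe that only cell 5
carries, and its sensed-temperature prediction can be compared against
the PT100 readings of all six cells.

Also houses the probe calibration (the in-line NIR LOD probe reports a
raw value that is mapped to reference LOD through an affine curve) and
the estimation-error metrics used to judge the observer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cell import Phase
from .line import LineInputs, LineParams, LineSchedule, SolverOptions, Trajectory, simulate_line


@dataclass(frozen=True)
class CalibrationCurve:
    """Affine calibration of the in-line LOD probe: LOD = slope*raw + intercept."""

    slope: float = 2.0218
    intercept: float = -1.571

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")

    def __call__(self, raw):
        return self.slope * np.asarray(raw, float) + self.intercept

    def inverse(self, calibrated):
        return (np.asarray(calibrated, float) - self.intercept) / self.slope


def lhp_calibrate(raw, curve: CalibrationCurve = CalibrationCurve()):
    """Calibrated LOD [%] from a raw probe reading [%]."""
    out = curve(raw)
    return float(out) if np.ndim(raw) == 0 else out


@dataclass
class SoftSensorOutput:
    """Per-cell predictions on the simulation output grid."""

    t: np.ndarray
    lod: np.ndarray           # (n_times, n_cells), NaN where the cell is empty
    T_sensed: np.ndarray      # (n_times, n_cells)
    T_ao_t: np.ndarray
    x_ao_t: np.ndarray
    phi_ao_t: np.ndarray
    trajectory: Trajectory

    def to_frame(self) -> pd.DataFrame:
        data: dict[str, np.ndarray] = {"time_s": self.t}
        for k in range(self.lod.shape[1]):
            data[f"lod_pred_pct_cell{k + 1}"] = self.lod[:, k]
        for k in range(self.T_sensed.shape[1]):
            data[f"T_sensed_pred_C_cell{k + 1}"] = self.T_sensed[:, k]
        data["T_ao_t_pred_C"] = self.T_ao_t
        data["x_ao_t_pred_kgkg"] = self.x_ao_t
        data["phi_ao_t_pred"] = self.phi_ao_t
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def run_trivial_observer(
    inputs: LineInputs,
    params: LineParams | None = None,
    schedule: LineSchedule | None = None,
    solver: SolverOptions | None = None,
    t_end: float | None = None,
) -> SoftSensorOutput:
    """Predict per-cell LOD and sensed temperatures from inputs alone."""
    traj = simulate_line(inputs, params=params, schedule=schedule,
                         solver=solver, t_end=t_end)
    return SoftSensorOutput(
        t=traj.t, lod=traj.lod, T_sensed=traj.T_sensed,
        T_ao_t=traj.T_ao_t, x_ao_t=traj.x_ao_t, phi_ao_t=traj.phi_ao_t,
        trajectory=traj,
    )


def _resample(t_src: np.ndarray, y_src: np.ndarray, t_dst: np.ndarray) -> np.ndarray:
    if len(t_dst) == 0:
        raise ValueError("no overlap between predicted and measured time grids")
    return np.interp(t_dst, t_src, y_src)


def estimation_errors(
    predicted: SoftSensorOutput | Trajectory,
    t_meas: np.ndarray,
    lod5_meas: np.ndarray,
    Tg5_meas: np.ndarray,
    cell: int = 5,
) -> dict:
    """Observer error series for the probe-equipped cell (default 5).

    e_w = predicted LOD - measured LOD [%] and e_Tg = predicted sensed
    temperature - measured cell temperature [degC], sign convention
    prediction minus measurement, on the measured time grid. Summary
    statistics (min/max/mean) are restricted to the drying phase, where
    the estimate matters operationally; filling/emptying samples and
    samples with undefined LOD are excluded.
    """
    traj = predicted.trajectory if isinstance(predicted, SoftSensorOutput) else predicted
    k = cell - 1
    t_meas = np.asarray(t_meas, float)
    inside = (t_meas >= traj.t[0]) & (t_meas <= traj.t[-1])
    if not inside.any():
        raise ValueError("no overlap between predicted and measured time grids")
    t_meas = t_meas[inside]
    lod5_meas = np.asarray(lod5_meas, float)[inside]
    Tg5_meas = np.asarray(Tg5_meas, float)[inside]

    lod_pred = _resample(traj.t, np.nan_to_num(traj.lod[:, k], nan=np.nan), t_meas)
    T_pred = _resample(traj.t, traj.T_sensed[:, k], t_meas)
    e_w = lod_pred - lod5_meas
    e_T = T_pred - Tg5_meas

    drying = _resample(traj.t, (traj.phase[:, k] == 1).astype(float), t_meas) >= 0.999
    valid = drying & np.isfinite(e_w)

    def _stats(e, m):
        sel = e[m]
        if sel.size == 0:
            return {"min": np.nan, "max": np.nan, "mean": np.nan, "n": 0}
        return {"min": float(sel.min()), "max": float(sel.max()),
                "mean": float(sel.mean()), "n": int(sel.size)}

    return {
        "t": t_meas, "e_w": e_w, "e_Tg": e_T, "drying_mask": valid,
        "summary": {"e_w": _stats(e_w, valid), "e_Tg": _stats(e_T, drying)},
    }
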