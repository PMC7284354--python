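"""YAML configuration round-trip for parameters, schedule and solver.

A single structured file covers everything a simulation or
identification run needs besides the input time series; fitted
parameters written by `fbdry identify` load back unchanged into
`fbdry simulate`.
"""

from __future__ import annotations

from dataclasses import asdict, fields, replace
from pathlib import Path

import yaml

from .cell import CellParams
from .line import LineParams, LineSchedule, SolverOptions
from .psychro import MoistAirConstants


def params_to_dict(params: LineParams, schedule: LineSchedule | None = None,
                   solver: SolverOptions | None = None) -> dict:
    out = {
        "cell": asdict(params.cell),
        "line": {
            "kV": params.kV, "alpha_in_e": params.alpha_in_e,
            "alpha_f_e": params.alpha_f_e, "Vdot_af": params.Vdot_af,
            "mdot_ap": params.mdot_ap, "T_gi": params.T_gi,
        },
        "constants": asdict(params.constants),
    }
    if schedule is not None:
        out["schedule"] = {
            "fill_switch_period": schedule.fill_switch_period,
            "empty_duration": schedule.empty_duration,
            "blowback_duration": schedule.blowback_duration,
            "n_cells": schedule.n_cells,
            "cell_order": list(schedule.order),
        }
    if solver is not None:
        d = asdict(solver)
        d["max_step"] = None if d["max_step"] == float("inf") else d["max_step"]
        out["solver"] = d
    return out


def params_from_dict(cfg: dict) -> tuple[LineParams, LineSchedule, SolverOptions]:
    cell = CellParams(**cfg.get("cell", {}))
    constants = MoistAirConstants(**cfg.get("constants", {}))
    params = LineParams(cell=cell, constants=constants, **cfg.get("line", {}))
    sched_cfg = dict(cfg.get("schedule", {}))
    if "cell_order" in sched_cfg and sched_cfg["cell_order"] is not None:
        sched_cfg["cell_order"] = tuple(sched_cfg["cell_order"])
    schedule = LineSchedule(**sched_cfg)
    solver_cfg = dict(cfg.get("solver", {}))
    if solver_cfg.get("max_step") is None:
        solver_cfg.pop("max_step", None)
    solver = SolverOptions(**solver_cfg)
    return params, schedule, solver


def save_config(path, params: LineParams, schedule: LineSchedule | None = None,
                solver: SolverOptions | None = None) -> None:
    Path(path).write_text(yaml.safe_dump(
        params_to_dict(params, schedule, solver), sort_keys=False))


def load_config(path) -> tuple[LineParams, LineSchedule, SolverOptions]:
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    return params_from_dict(cfg)
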