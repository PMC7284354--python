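"""Weighted min-max (Chebyshev) parameter identification.

Seven parameters are fitted to measured line trajectories: the
drying-rate coefficient km, the air-granule and wall heat-transfer
coefficients kag and kloss, the air-temperature blend weight k1, the
per-cell air holdup ma, the volume-flow correction kV, and the sensor
blend weight ksep. Four weighted sum-of-squares terms are formed —
outlet air temperature (weight 0.25), outlet air water content (weight
1000), the six sensed cell temperatures (weight 1), and the probe LOD
of cell 5 over its drying-validity mask (weight 2) — and the LARGEST of
the four is minimized:

    min_params  max(F1, F2, F3, F4).

The weights put the water-content error on the same numerical scale as
the temperature errors and emphasize the LOD, the quantity of primary
interest.

All searching happens in a transformed space -- log for the strictly
positive km, kag, kloss, ma and scaled logit for the bounded k1, ksep,
kV -- which enforces the bounds without constraints and makes the
search invariant to the parameters' units. The minimization itself is
two-stage: a Gauss-Newton descent (trust-region least squares) on the
stacked weighted residual vector, whose sum of squares F1+F2+F3+F4
shares its minimizer with max_i F_i whenever the model can drive all
four terms toward zero, followed by a derivative-free adaptive
Nelder-Mead polish on max_i F_i itself, which settles the genuinely
nonsmooth Chebyshev criterion when the terms cannot all vanish.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares, minimize

from .line import LineParams, LineSchedule, SolverOptions, simulate_line

log = logging.getLogger(__name__)

FIT_PARAM_NAMES = ("km", "kag", "kloss", "k1", "ma", "kV", "ksep")
#: objective value returned when a candidate simulation fails
PENALTY = 1e12


@dataclass
class IdentDataset:
    """Measured streams + inputs over an evaluation window.

    ``t`` is the native measurement grid (uniform). ``lod5_mask`` marks
    the samples where the cell-5 probe LOD is valid ("drying" interval).
    The window [t_start, t_end] excludes e.g. the line heat-up phase.
    """

    inputs: LineInputs
    t: np.ndarray
    T_ao_t: np.ndarray
    x_ao_t: np.ndarray
    Tg: np.ndarray            # (n_times, 6) sensed cell temperatures
    lod5: np.ndarray
    lod5_mask: np.ndarray
    t_start: float = 0.0
    t_end: float | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        if self.t_end is None:
            self.t_end = float(self.t[-1])
        if not np.any(self.window_mask() & self.lod5_mask):
            raise ValueError("LOD validity mask is empty within the evaluation window")

    def window_mask(self) -> np.ndarray:
        return (self.t >= self.t_start) & (self.t <= self.t_end)


@dataclass(frozen=True)
class ObjectiveWeights:
    """Empirical weights of the four objective terms (inside the square)."""

    w_T_out: float = 0.25
    w_x_out: float = 1000.0
    w_Tg: float = 1.0
    w_LOD: float = 2.0

    def __post_init__(self) -> None:
        if min(self.w_T_out, self.w_x_out, self.w_Tg, self.w_LOD) <= 0:
            raise ValueError("objective weights must be strictly positive")


def apply_params(base: LineParams, values: dict[str, float]) -> LineParams:
    """Return a copy of ``base`` with the fitted coordinates replaced."""
    cell_updates = {k: v for k, v in values.items()
                    if k in ("km", "kag", "kloss", "k1", "ma", "ksep")}
    out = replace(base, cell=replace(base.cell, **cell_updates))
    if "kV" in values:
        out = replace(out, kV=values["kV"])
    return out


def extract_params(params: LineParams) -> dict[str, float]:
    c = params.cell
    return {"km": c.km, "kag": c.kag, "kloss": c.kloss, "k1": c.k1,
            "ma": c.ma, "kV": params.kV, "ksep": c.ksep}


def _weighted_residual_blocks(
    params: LineParams,
    dataset: IdentDataset,
    weights: ObjectiveWeights,
    schedule: LineSchedule | None,
    solver: SolverOptions,
) -> list[np.ndarray] | None:
    """Four blocks of weighted residuals (measurement minus model).

    One line simulation over the dataset horizon, model outputs
    interpolated to the measurement grid, each block already multiplied
    by its weight so that F_i = sum(block_i**2). None on failure.
    """
    try:
        traj = simulate_line(dataset.inputs, params=params, schedule=schedule,
                             solver=solver, t_end=dataset.t_end)
    except (RuntimeError, ValueError) as exc:
        log.warning("simulation failed during identification: %s", exc)
        return None

    w = dataset.window_mask()
    tm = dataset.t[w]

    def interp(series):
        return np.interp(tm, traj.t, series)

    r1 = weights.w_T_out * (dataset.T_ao_t[w] - interp(traj.T_ao_t))
    r2 = weights.w_x_out * (dataset.x_ao_t[w] - interp(traj.x_ao_t))
    # model-side sensed temperature: ksep blend + 30 s first-order lag,
    # evaluated by the simulator on its own grid
    r3 = np.concatenate([
        weights.w_Tg * (dataset.Tg[w, k] - interp(traj.T_sensed[:, k]))
        for k in range(traj.Tg.shape[1])])
    m4 = w & dataset.lod5_mask
    lod_pred = np.interp(dataset.t[m4], traj.t, np.nan_to_num(traj.lod[:, 4], nan=0.0))
    r4 = weights.w_LOD * (dataset.lod5[m4] - lod_pred)
    blocks = [r1, r2, r3, r4]
    if not all(np.all(np.isfinite(b)) for b in blocks):
        return None
    return blocks


def objective_components(
    params: LineParams,
    dataset: IdentDataset,
    weights: ObjectiveWeights = ObjectiveWeights(),
    schedule: LineSchedule | None = None,
    solver: SolverOptions | None = None,
) -> np.ndarray:
    """Evaluate (F1, F2, F3, F4) for one candidate parameter set.

    Runs one line simulation over the dataset horizon, interpolates the
    model outputs to the measurement grid, and forms the four weighted
    sum-of-squares over the evaluation window. A failed simulation
    yields a large-penalty sentinel so derivative-free optimizers can
    step over it.
    """
    blocks = _weighted_residual_blocks(params, dataset, weights, schedule,
                                       solver or SolverOptions())
    if blocks is None:
        return np.full(4, PENALTY)
    return np.array([float(np.sum(b ** 2)) for b in blocks])


# -- parameter transforms ---------------------------------------------------

_LOG_PARAMS = ("km", "kag", "kloss", "ma")
_LOGIT_PARAMS = {"k1": 1.0, "ksep": 1.0, "kV": 2.0}  # upper bound of (0, hi)


def _to_internal(values: dict[str, float]) -> np.ndarray:
    z = []
    for name in FIT_PARAM_NAMES:
        v = values[name]
        if name in _LOG_PARAMS:
            z.append(np.log(v))
        else:
            hi = _LOGIT_PARAMS[name]
            q = np.clip(v / hi, 1e-9, 1 - 1e-9)
            z.append(np.log(q / (1 - q)))
    return np.array(z)


def _from_internal(z: np.ndarray) -> dict[str, float]:
    values = {}
    for name, zi in zip(FIT_PARAM_NAMES, z):
        if name in _LOG_PARAMS:
            values[name] = float(np.exp(zi))
        else:
            hi = _LOGIT_PARAMS[name]
            values[name] = float(hi / (1.0 + np.exp(-zi)))
    return values


@dataclass
class IdentResult:
    params: LineParams
    values: dict[str, float]
    F: np.ndarray
    max_F: float
    n_evals: int
    converged: bool
    history: list = field(default_factory=list)


def minmax_identify(
    dataset: IdentDataset,
    initial: LineParams | None = None,
    weights: ObjectiveWeights = ObjectiveWeights(),
    schedule: LineSchedule | None = None,
    solver: SolverOptions | None = None,
    maxiter: int = 150,
    lsq_nfev: int = 40,
    xatol: float = 1e-4,
    fatol: float = 1e-12,
) -> IdentResult:
    """Minimize max(F1..F4) over the seven parameters.

    Stage 1: trust-region least squares on the stacked weighted
    residuals (finite-difference Jacobian, ``lsq_nfev`` residual
    evaluations at most, each costing 1 + 7 simulations when the
    Jacobian is refreshed). Stage 2: adaptive Nelder-Mead on max(F_i)
    from the stage-1 point (``maxiter`` iterations). On non-convergence
    the best point seen is returned with ``converged=False``.
    """
    base = initial or LineParams()
    history: list[tuple[float, np.ndarray]] = []
    n_evals = 0
    solver = solver or SolverOptions()

    def residuals(z: np.ndarray) -> np.ndarray:
        nonlocal n_evals
        n_evals += 1
        blocks = _weighted_residual_blocks(apply_params(base, _from_internal(z)),
                                           dataset, weights, schedule, solver)
        if blocks is None:
            return np.full(1, 1e6)  # never reached with finite starting points
        history.append((max(float(np.sum(b ** 2)) for b in blocks),
                        np.array([float(np.sum(b ** 2)) for b in blocks])))
        return np.concatenate(blocks)

    def chebyshev(z: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        F = objective_components(apply_params(base, _from_internal(z)), dataset,
                                 weights, schedule=schedule, solver=solver)
        m = float(F.max())
        history.append((m, F))
        return m

    z0 = _to_internal(extract_params(base))
    if lsq_nfev > 0:
        lsq = least_squares(residuals, z0, method="trf",
                            max_nfev=lsq_nfev, xtol=1e-12, ftol=1e-12, gtol=1e-12)
        z0 = lsq.x
    res = minimize(chebyshev, z0, method="Nelder-Mead",
                   options={"maxiter": maxiter, "adaptive": True,
                            "xatol": xatol, "fatol": fatol})
    values = _from_internal(res.x)
    fitted = apply_params(base, values)
    # re-evaluate at the returned point: the reported F must never be stale
    F = objective_components(fitted, dataset, weights, schedule=schedule, solver=solver)
    converged = bool(np.all(F < PENALTY)) and np.isfinite(F).all()
    if not converged:
        log.warning("min-max identification did not fully converge; returning best-so-far")
    return IdentResult(params=fitted, values=values, F=F, max_F=float(F.max()),
                       n_evals=n_evals, converged=converged, history=history)
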