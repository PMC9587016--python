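"""Regularized multi-start parameter estimation.

The data misfit is a max-normalized least-squares cost

    C(theta) = sum_i sum_j ((y_sim(i, t_ij) - y_obs(i,j)) / max_j y_obs(i,.))^2

over the M measured metabolites.  Physiology-informed regularization appends
four penalty residuals that (i) force the glucose meal mass to appear from
the gut within 4 h, (ii) force the TG meal mass to appear via the lymph
within 10 h, and (iii-iv) force plasma TG at 12 h and NEFA at t=0 back to
the fasting values.  Penalties are implemented as normalized, weighted
residuals (the squared-sum of the full residual vector is the regularized
cost C*), so they are sign-symmetric and compatible with a least-squares
solver.

Optimization runs a bounded trust-region-reflective least-squares solver in
log10 parameter space from Latin-hypercube starting points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .model import MU_TO_PMOL, BasalInfeasibleError
from .parameters import ParameterSet, default_parameters
from .simulate import (SimulationError, SimulationResult,
                       cumulative_appearance, simulate)
from .types import MealResponse

__all__ = ["FitData", "FitConfig", "FitResult", "StartRecord", "cost",
           "regularized_residuals", "lhs_starts", "fit"]

# measured responses double as fit data: per-metabolite time/value arrays
# plus the subject constants and meal composition
FitData = MealResponse

#: residual value substituted when a candidate cannot be simulated; large
#: enough that such points never win the multi-start, finite so the solver
#: survives them
_SENTINEL = 1.0e3

# penalty evaluation horizon: glucose AUC at 240 min, TG AUC at 600 min,
# TG steady-state check at 720 min
_PENALTY_TIMES = (240.0, 600.0, 720.0)


@dataclass
class FitConfig:
    """Estimation settings.

    free: parameter names to estimate (None = the registry's free flags).
    n_starts: number of Latin-hypercube initializations.
    regularize: include the four physiology penalties.
    penalty_weights: (glucose AUC, TG AUC, TG steady state, NEFA basal).
    """

    free: tuple[str, ...] | None = None
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_starts: int = 25
    seed: int = 0
    regularize: bool = True
    penalty_weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    max_nfev: int = 400
    diff_step: float = 1e-3
    ftol: float = 1e-12
    xtol: float = 1e-12
    rtol: float = 1e-6
    atol: float = 1e-8

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if any(w < 0 for w in self.penalty_weights):
            raise ValueError("penalty weights must be >= 0")

    def resolve(self, params: ParameterSet) -> tuple[tuple[str, ...], np.ndarray]:
        """Free-parameter names and their (log10) bounds as a (2, k) array."""
        free = tuple(self.free) if self.free is not None else params.free_names
        lo, hi = [], []
        for name in free:
            l, h = self.bounds.get(name, params.bounds(name))
            if not (0 < l <= h) or not np.isfinite(h):
                raise ValueError(f"{name}: bounds must be finite and positive")
            lo.append(l)
            hi.append(h)
        return free, np.log10(np.array([lo, hi]))


def _fit_grid(data: FitData, regularize: bool) -> np.ndarray:
    """Reporting grid for one cost evaluation: a 4-min lattice (dense enough
    for the appearance-flux quadrature) merged with the observation times."""
    t_max = max(g[-1] for g in data.times.values())
    if regularize:
        t_max = max(t_max, _PENALTY_TIMES[-1])
    lattice = np.arange(0.0, t_max + 2.0, 4.0)
    pts = np.unique(np.concatenate([lattice, [t_max]]
                                   + [g for g in data.times.values()]))
    return pts[pts <= t_max + 1e-9]


def _data_residuals(result: SimulationResult, data: FitData) -> np.ndarray:
    out = []
    for m in data.metabolites:
        y_obs = data.values[m]
        y_max = y_obs.max()
        if y_max <= 0:
            raise ValueError(f"{m}: all observations zero; cannot normalize")
        y_sim = result.interp(m, data.times[m])
        out.append((y_sim - y_obs) / y_max)
    return np.concatenate(out)


def _penalty_residuals(result: SimulationResult, data: FitData,
                       weights) -> np.ndarray:
    meal, subject = data.meal, data.subject
    pen = np.zeros(4)
    if meal.G_meal > 0:
        auc_g = cumulative_appearance(result, "glucose", 240.0)
        pen[0] = weights[0] * (auc_g - meal.G_meal) / meal.G_meal
    elif weights[0] > 0:
        warnings.warn("zero glucose meal mass: glucose-AUC penalty skipped")
    if meal.TG_meal > 0:
        auc_tg = cumulative_appearance(result, "tg", 600.0)
        pen[1] = weights[1] * (auc_tg - meal.TG_meal) / meal.TG_meal
    elif weights[1] > 0:
        warnings.warn("zero TG meal mass: TG-AUC penalty skipped")
    tg720 = result.interp("tg", np.array([720.0]))[0]
    pen[2] = weights[2] * (tg720 - subject.TG_b) / subject.TG_b
    nefa0 = result.interp("nefa", np.array([0.0]))[0]
    pen[3] = weights[3] * (nefa0 - subject.NEFA_b) / subject.NEFA_b
    return pen


def _simulate_for(params: ParameterSet, data: FitData, regularize: bool,
                  rtol: float = 1e-6, atol: float = 1e-8) -> SimulationResult:
    grid = _fit_grid(data, regularize)
    return simulate(params, data.subject, data.meal, t_end=grid[-1],
                    grid=grid, rtol=rtol, atol=atol)


def cost(params: ParameterSet, data: FitData) -> float:
    """Max-normalized sum-of-squares data misfit C(theta)."""
    r = regularized_residuals(params, data, FitConfig(regularize=False))
    return float(r @ r)


def regularized_residuals(params: ParameterSet, data: FitData,
                          config: FitConfig | None = None) -> np.ndarray:
    """Normalized data residuals concatenated with the four physiology
    penalty residuals; sum of squares is the regularized cost C*."""
    config = config if config is not None else FitConfig()
    result = _simulate_for(params, data, regularize=True,
                           rtol=config.rtol, atol=config.atol)
    r = _data_residuals(result, data)
    if not config.regularize:
        return r
    return np.concatenate([r, _penalty_residuals(result, data,
                                                 config.penalty_weights)])


def lhs_starts(n: int, bounds: dict[str, tuple[float, float]],
               seed: int | None = None) -> np.ndarray:
    """Latin-hypercube start points, stratified in log-space of the bounds.

    Returns an (n, k) array in linear parameter units; column order follows
    the dict order of `bounds`.  Degenerate bounds (low == high) give a
    fixed coordinate.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    names = list(bounds)
    lo = np.array([bounds[k][0] for k in names], dtype=float)
    hi = np.array([bounds[k][1] for k in names], dtype=float)
    if np.any(lo <= 0) or np.any(~np.isfinite(hi)):
        raise ValueError("bounds must be finite and positive")
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    u = sampler.random(n)
    log_lo, log_hi = np.log10(lo), np.log10(hi)
    return 10.0 ** (log_lo + u * (log_hi - log_lo))


@dataclass
class StartRecord:
    start: dict[str, float]
    solution: dict[str, float]
    cost: float
    converged: bool
    message: str
    nfev: int


@dataclass
class FitResult:
    """Best parameters plus the full multi-start ledger."""

    params: ParameterSet
    best_cost: float
    data_cost: float
    penalty_cost: float
    starts: list[StartRecord]
    free: tuple[str, ...]
    config: FitConfig
    data: FitData

    @property
    def best_values(self) -> dict[str, float]:
        return {n: self.params[n] for n in self.free}


def _closure_violation(params: ParameterSet, data: FitData) -> float:
    """Relative amount by which the candidate violates the basal feasibility
    constraints (0 when the fasting closure exists)."""
    s = data.subject
    lpl_need = params["k16"] / s.TG_b
    lpl_have = params["k11"] * MU_TO_PMOL * s.I_b
    atl = params["k12"] * s.NEFA_b - 3.0 * params["f_spill"] * params["k16"]
    v = max(0.0, (lpl_have - lpl_need) / max(lpl_need, 1e-12))
    v += max(0.0, -atl / max(params["k12"] * s.NEFA_b, 1e-12))
    return v


def _make_residual_fn(base: ParameterSet, data: FitData, config: FitConfig,
                      free: tuple[str, ...], n_res: int):
    def residual(z: np.ndarray) -> np.ndarray:
        values = dict(zip(free, 10.0 ** z))
        try:
            candidate = base.with_values(values)
            return regularized_residuals(candidate, data, config)
        except BasalInfeasibleError:
            # graded sentinel: slopes back toward the feasible region
            v = _closure_violation(base.with_values(values), data)
            return np.full(n_res, _SENTINEL * (1.0 + v))
        except (SimulationError, ValueError):
            return np.full(n_res, _SENTINEL)
    return residual


def fit(data: FitData, config: FitConfig | None = None,
        params: ParameterSet | None = None) -> FitResult:
    """Multi-start bounded least-squares estimation.

    Runs a trust-region-reflective solver in log10 parameter space from
    `config.n_starts` Latin-hypercube initializations and returns the best
    converged solution together with the per-start ledger.
    """
    config = config if config is not None else FitConfig()
    base = params if params is not None else default_parameters()
    free, log_bounds = config.resolve(base)

    n_data = sum(len(v) for m, v in data.values.items())
    n_res = n_data + (4 if config.regularize else 0)
    residual = _make_residual_fn(base, data, config, free, n_res)

    bounds_dict = {name: tuple(10.0 ** log_bounds[:, i])
                   for i, name in enumerate(free)}
    starts = lhs_starts(config.n_starts, bounds_dict, seed=config.seed)

    records: list[StartRecord] = []
    for x0 in starts:
        z0 = np.log10(x0)
        try:
            sol = least_squares(residual, z0, bounds=(log_bounds[0], log_bounds[1]),
                                method="trf", max_nfev=config.max_nfev,
                                ftol=config.ftol, xtol=config.xtol, gtol=1e-12,
                                diff_step=config.diff_step)
            c = float(sol.fun @ sol.fun)
            converged = bool(sol.success) and c < 0.5 * n_res * _SENTINEL ** 2
            records.append(StartRecord(
                start=dict(zip(free, x0)),
                solution=dict(zip(free, 10.0 ** sol.x)),
                cost=c, converged=converged,
                message=str(sol.message), nfev=int(sol.nfev)))
        except Exception as exc:  # solver blow-up: log and move on
            records.append(StartRecord(
                start=dict(zip(free, x0)), solution=dict(zip(free, x0)),
                cost=np.inf, converged=False, message=repr(exc), nfev=0))

    ok = [r for r in records if r.converged]
    if not ok:
        err = RuntimeError("all optimization starts failed")
        err.starts = records
        raise err
    best = min(ok, key=lambda r: r.cost)
    best_params = base.with_values(best.solution).with_free(free)

    res = _simulate_for(best_params, data, regularize=True,
                        rtol=config.rtol, atol=config.atol)
    r_data = _data_residuals(res, data)
    data_cost = float(r_data @ r_data)
    if config.regularize:
        pen = _penalty_residuals(res, data, config.penalty_weights)
        penalty_cost = float(pen @ pen)
    else:
        penalty_cost = 0.0
    return FitResult(params=best_params, best_cost=best.cost,
                     data_cost=data_cost, penalty_cost=penalty_cost,
                     starts=records, free=free, config=config, data=data)
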