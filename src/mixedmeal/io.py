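"""File formats: meal-response CSV, fit reports (JSON), trajectory export.

The response CSV dialect is one row per blood draw: columns ``time_min,
glucose_mmol_L, insulin_mU_L, tg_mmol_L, nefa_mmol_L``, comma-separated,
UTF-8, '.' decimal; empty cells mark metabolites not measured at that draw
(sparser TG/NEFA grids).  Fit reports are schema-versioned JSON
("mmm-report/1") embedding the configuration and seed so a run is fully
reproducible from its report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .estimate import FitConfig, FitResult, StartRecord
from .parameters import default_parameters
from .simulate import SimulationResult
from .types import MealResponse, MealSpec, SubjectSpec

__all__ = ["read_meal_response", "write_meal_response", "write_fit_report",
           "load_fit_report", "write_trajectory", "REPORT_SCHEMA"]

REPORT_SCHEMA = "mmm-report/1"

_COLUMNS = {
    "glucose": "glucose_mmol_L",
    "insulin": "insulin_mU_L",
    "tg": "tg_mmol_L",
    "nefa": "nefa_mmol_L",
}


def read_meal_response(path, subject: SubjectSpec | None = None,
                       meal: MealSpec | None = None) -> MealResponse:
    """Read a meal-response CSV; empty cells are treated as missing and
    dropped from the per-metabolite series."""
    df = pd.read_csv(path)
    unknown = set(df.columns) - {"time_min", *_COLUMNS.values()}
    if unknown:
        raise ValueError(f"unknown column(s) {sorted(unknown)} in {path}")
    if "time_min" not in df.columns:
        raise ValueError(f"missing required column time_min in {path}")
    t = df["time_min"].to_numpy(dtype=float)
    if np.any(~np.isfinite(t)) or np.any(np.diff(t) <= 0) or np.any(t < 0):
        raise ValueError("time_min must be non-negative and strictly increasing")
    if df.drop(columns="time_min").isna().all(axis=1).any():
        raise ValueError("every row must have at least one measured value")

    times, values = {}, {}
    for metab, col in _COLUMNS.items():
        if col not in df.columns:
            continue
        y = df[col].to_numpy(dtype=float)
        keep = np.isfinite(y)
        if not keep.any():
            continue
        if np.any(y[keep] < 0):
            raise ValueError(f"{col}: negative concentration")
        times[metab] = t[keep]
        values[metab] = y[keep]
    kwargs = {}
    if subject is not None:
        kwargs["subject"] = subject
    if meal is not None:
        kwargs["meal"] = meal
    return MealResponse(times=times, values=values, **kwargs)


def write_meal_response(response: MealResponse, path) -> None:
    """Write the CSV dialect (one row per distinct time; unmeasured cells
    left empty)."""
    all_t = np.unique(np.concatenate(list(response.times.values())))
    df = pd.DataFrame({"time_min": all_t})
    for metab, col in _COLUMNS.items():
        if metab not in response.times:
            continue
        series = np.full(all_t.size, np.nan)
        idx = np.searchsorted(all_t, response.times[metab])
        series[idx] = response.values[metab]
        df[col] = series
    df.to_csv(path, index=False)


def write_trajectory(result: SimulationResult, path) -> None:
    """Tidy long-format trajectory CSV (time, variable, value) with the 13
    states and the 10 named fluxes."""
    result.to_frame().to_csv(path, index=False)


def _config_dict(config: FitConfig) -> dict:
    d = dataclasses.asdict(config)
    d["free"] = list(config.free) if config.free is not None else None
    d["penalty_weights"] = list(config.penalty_weights)
    d["bounds"] = {k: list(v) for k, v in config.bounds.items()}
    return d


def _config_hash(config_dict: dict) -> str:
    blob = json.dumps(config_dict, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_fit_report(fit_result: FitResult, profiles=None, path=None,
                     trajectory_path=None) -> dict:
    """Serialize a FitResult (and optional profile results) to JSON.

    Returns the report dict; writes it to `path` when given, and exports the
    fitted simulation's states and fluxes as tidy CSV to `trajectory_path`
    when given.
    """
    from .estimate import _simulate_for

    cfg = _config_dict(fit_result.config)
    report = {
        "schema": REPORT_SCHEMA,
        "seed": fit_result.config.seed,
        "config": cfg,
        "config_hash": _config_hash(cfg),
        "free": list(fit_result.free),
        "parameters": fit_result.params.as_dict(),
        "best_cost": fit_result.best_cost,
        "data_cost": fit_result.data_cost,
        "penalty_cost": fit_result.penalty_cost,
        "subject": dataclasses.asdict(fit_result.data.subject),
        "meal": dataclasses.asdict(fit_result.data.meal),
        "starts": [dataclasses.asdict(s) for s in fit_result.starts],
    }
    if profiles:
        report["profiles"] = [
            {"param": p.param, "grid": p.grid.tolist(),
             "cost": np.where(np.isfinite(p.cost), p.cost, None).tolist(),
             "best_cost": p.best_cost, "best_value": p.best_value,
             "threshold": p.threshold, "verdict": p.verdict,
             "flags": list(p.flags)}
            for p in profiles
        ]
    if path is not None:
        Path(path).write_text(json.dumps(report, indent=2))
    if trajectory_path is not None:
        res = _simulate_for(fit_result.params, fit_result.data,
                            regularize=True)
        write_trajectory(res, trajectory_path)
    return report


def load_fit_report(path, data: MealResponse) -> FitResult:
    """Rebuild a FitResult from a report JSON plus the response it fitted."""
    report = json.loads(Path(path).read_text())
    if report.get("schema") != REPORT_SCHEMA:
        raise ValueError(f"unsupported report schema {report.get('schema')!r}")
    cfg_d = dict(report["config"])
    cfg_d["free"] = tuple(cfg_d["free"]) if cfg_d["free"] else None
    cfg_d["penalty_weights"] = tuple(cfg_d["penalty_weights"])
    cfg_d["bounds"] = {k: tuple(v) for k, v in cfg_d["bounds"].items()}
    config = FitConfig(**cfg_d)
    free = tuple(report["free"])
    params = default_parameters().with_values(report["parameters"]).with_free(free)
    starts = [StartRecord(**s) for s in report["starts"]]
    return FitResult(params=params, best_cost=report["best_cost"],
                     data_cost=report["data_cost"],
                     penalty_cost=report["penalty_cost"], starts=starts,
                     free=free, config=config, data=data)
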