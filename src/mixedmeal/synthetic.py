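"""Synthetic meal-challenge fixtures.

The two cohort studies this package is designed around are not publicly
deposited, so this module emulates their sampling designs and phenotype
subgroup parameter estimates: a 6-sample 0-480 min design with a
75 g glucose / 60 g lipid / 20 g protein liquid meal ("nutritech"), and a
denser 0-300 min design (10 glucose/insulin samples, 7 TG/NEFA samples) with
a 67/36/12 g meal ("metflex").  Phenotype presets carry the published
subgroup estimates of k5, k6, k11, K_ATL and k16; subject fasting values per
phenotype are fabricated defaults (the source reports them only graphically)
and documented as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import BasalInfeasibleError
from .parameters import ParameterSet, default_parameters
from .simulate import simulate
from .types import (METABOLITES, METFLEX_MEAL, NUTRITECH_MEAL, MealResponse,
                    MealSpec, SubjectSpec)

__all__ = ["StudyDesign", "PhenotypePreset", "NoiseModel", "DESIGNS",
           "PRESETS", "design", "preset", "generate_response",
           "generate_cohort", "CohortSample"]


@dataclass(frozen=True)
class StudyDesign:
    """Named sampling design: per-metabolite blood-draw grids (min) + meal."""

    name: str
    grids: dict[str, np.ndarray]
    meal: MealSpec

    def __post_init__(self) -> None:
        for m, g in self.grids.items():
            g = np.asarray(g, dtype=float)
            if m not in METABOLITES:
                raise ValueError(f"unknown metabolite {m!r}")
            if g[0] != 0 or np.any(np.diff(g) <= 0):
                raise ValueError(f"{m}: grid must start at 0 and increase")
            self.grids[m] = g

    @property
    def t_max(self) -> float:
        return max(g[-1] for g in self.grids.values())


def _make_designs() -> dict[str, StudyDesign]:
    nutritech_grid = np.array([0.0, 60, 120, 240, 360, 480])
    metflex_gi = np.array([0.0, 15, 30, 45, 60, 90, 120, 180, 240, 300])
    metflex_lipid = np.array([0.0, 30, 60, 120, 180, 240, 300])
    return {
        "nutritech": StudyDesign(
            "nutritech",
            {m: nutritech_grid.copy() for m in METABOLITES},
            NUTRITECH_MEAL),
        "metflex": StudyDesign(
            "metflex",
            {"glucose": metflex_gi.copy(), "insulin": metflex_gi.copy(),
             "tg": metflex_lipid.copy(), "nefa": metflex_lipid.copy()},
            METFLEX_MEAL),
    }


DESIGNS = _make_designs()


def design(name: str) -> StudyDesign:
    try:
        return DESIGNS[name]
    except KeyError:
        raise KeyError(
            f"unknown design {name!r}; available: {sorted(DESIGNS)}") from None


@dataclass(frozen=True)
class PhenotypePreset:
    """Subgroup parameter overrides plus subject fasting values.

    `overrides` are the published subgroup estimates (k5, k6, k11, K_ATL,
    k16); `subject` fasting concentrations are fabricated defaults chosen to
    be typical of the phenotype, not published values.
    """

    name: str
    overrides: dict[str, float]
    subject: SubjectSpec

    def parameters(self, base: ParameterSet | None = None) -> ParameterSet:
        base = base if base is not None else default_parameters()
        return base.with_values(self.overrides)


# fabricated fasting phenotypes (G_b mmol/L, I_b mU/L, TG_b mmol/L,
# NEFA_b mmol/L, BW kg): "sensitive"-like, intermediate, "resistant"-like
_SUBJ_SENSITIVE = SubjectSpec(5.0, 8.0, 1.3, 0.45, 85.0)
_SUBJ_AVERAGE = SubjectSpec(5.3, 10.0, 1.5, 0.50, 85.0)
_SUBJ_RESISTANT = SubjectSpec(5.6, 14.0, 1.8, 0.55, 85.0)

# published subgroup estimates: (k5, k6, k11, K_ATL, k16)
_PRESET_TABLE = {
    "metflex_insulin_sensitive":  ((0.142, 2.204, 1.4e-4, 0.130, 0.014), _SUBJ_SENSITIVE),
    "metflex_insulin_resistant":  ((0.073, 4.304, 5.2e-5, 0.124, 0.018), _SUBJ_RESISTANT),
    "metflex_population":         ((0.102, 2.852, 8.3e-5, 0.126, 0.015), _SUBJ_AVERAGE),
    "nutritech_insulin_sensitive": ((0.073, 1.966, 8.2e-5, 0.099, 0.010), _SUBJ_SENSITIVE),
    "nutritech_insulin_resistant": ((0.025, 2.592, 2.3e-5, 0.026, 0.013), _SUBJ_RESISTANT),
    "nutritech_population":        ((0.042, 2.413, 4.6e-5, 0.041, 0.012), _SUBJ_AVERAGE),
    "nutritech_lower_liver_fat":   ((0.067, 2.351, 8.0e-5, 0.057, 0.011), _SUBJ_SENSITIVE),
    "nutritech_higher_liver_fat":  ((0.028, 2.961, 2.9e-5, 0.038, 0.014), _SUBJ_RESISTANT),
}

PRESETS = {
    name: PhenotypePreset(
        name,
        dict(zip(("k5", "k6", "k11", "K_ATL", "k16"), values)),
        subject,
    )
    for name, (values, subject) in _PRESET_TABLE.items()
}


def preset(name: str) -> PhenotypePreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative Gaussian measurement noise, one CV per metabolite.

    Default CVs resemble clinical assay precision: glucose 3%, insulin 8%,
    TG 5%, NEFA 8%.
    """

    cv: dict[str, float] = field(default_factory=lambda: {
        "glucose": 0.03, "insulin": 0.08, "tg": 0.05, "nefa": 0.08})

    def __post_init__(self) -> None:
        for m, v in self.cv.items():
            if m not in METABOLITES or v < 0:
                raise ValueError(f"invalid noise entry {m}={v}")

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        return cls({m: 0.0 for m in METABOLITES})


def generate_response(design: StudyDesign, preset: PhenotypePreset,
                      noise: NoiseModel | None = None,
                      seed: int | None = None,
                      subject: SubjectSpec | None = None,
                      params: ParameterSet | None = None) -> MealResponse:
    """Simulate one meal challenge and sample it on the design's grids.

    Multiplicative Gaussian noise (per-metabolite CV) is applied and the
    result clipped at zero; deterministic under a fixed seed.  `subject` and
    `params` override the preset's when given.
    """
    noise = noise if noise is not None else NoiseModel()
    subject = subject if subject is not None else preset.subject
    params = params if params is not None else preset.parameters()
    rng = np.random.default_rng(seed)

    res = simulate(params, subject, design.meal, t_end=design.t_max)
    times, values = {}, {}
    for m, grid in design.grids.items():
        y = res.interp(m, grid)
        cv = noise.cv.get(m, 0.0)
        if cv > 0:
            y = y * (1.0 + cv * rng.standard_normal(y.shape))
        times[m] = grid.copy()
        values[m] = np.maximum(y, 0.0)
    return MealResponse(times=times, values=values, subject=subject,
                        meal=design.meal)


@dataclass
class CohortSample:
    """Cohort fixture: per-subject responses, their true parameters, and the
    cohort-mean response used for group-average fitting."""

    responses: list[MealResponse]
    true_parameters: list[dict[str, float]]
    mean_response: MealResponse


def generate_cohort(design: StudyDesign, preset: PhenotypePreset, n: int,
                    between_cv: float = 0.15,
                    noise: NoiseModel | None = None,
                    seed: int | None = None) -> CohortSample:
    """Sample `n` subjects with log-normal between-subject parameter spread
    around the preset (free parameters only), plus the cohort-mean response.

    The mean response averages the per-subject sampled concentrations on the
    shared design grids, mirroring group-average curve fitting.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    base = preset.parameters()
    sigma = np.sqrt(np.log1p(between_cv ** 2))  # log-normal with unit median

    responses, truths = [], []
    for i in range(n):
        # redraw on the rare parameter combination whose basal closure is
        # infeasible for this subject (e.g. LPL drive exceeding k16)
        for _attempt in range(100):
            values = {}
            for name in base.free_names:
                lo, hi = base.bounds(name)
                draw = base[name] * np.exp(sigma * rng.standard_normal()) if sigma > 0 else base[name]
                values[name] = float(np.clip(draw, lo, hi))
            params_i = base.with_values(values)
            try:
                resp = generate_response(design, preset, noise=noise,
                                         seed=int(rng.integers(2 ** 31)),
                                         params=params_i)
            except BasalInfeasibleError:
                continue
            break
        else:
            raise BasalInfeasibleError(
                "could not draw a feasible subject in 100 attempts")
        responses.append(resp)
        truths.append(params_i.as_dict())

    mean_values = {
        m: np.mean([r.values[m] for r in responses], axis=0)
        for m in design.grids
    }
    mean_response = MealResponse(
        times={m: g.copy() for m, g in design.grids.items()},
        values=mean_values, subject=preset.subject, meal=design.meal)
    return CohortSample(responses=responses, true_parameters=truths,
                        mean_response=mean_response)
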