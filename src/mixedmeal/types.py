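"""Subject, meal and measured-response containers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SubjectSpec", "MealSpec", "MealResponse", "METABOLITES",
           "GLUCOSE_MOLAR_MASS", "TG_MOLAR_MASS"]

#: canonical metabolite order used throughout (plasma concentrations)
METABOLITES = ("glucose", "insulin", "tg", "nefa")

#: g/mol, for gram <-> mmol conversion of meal glucose
GLUCOSE_MOLAR_MASS = 180.16
#: g/mol, generic triglyceride
TG_MOLAR_MASS = 860.0


@dataclass(frozen=True)
class SubjectSpec:
    """Fasting (basal) plasma concentrations and body weight.

    Units: glucose mmol/L, insulin mU/L, TG mmol/L, NEFA mmol/L, weight kg.
    Basal glucose and insulin are fixed to the measured overnight-fast values;
    basal TG and NEFA anchor the lipid steady state.
    """

    G_b: float = 5.0
    I_b: float = 8.0
    TG_b: float = 1.3
    NEFA_b: float = 0.45
    BW: float = 85.0

    def __post_init__(self) -> None:
        for name in ("G_b", "I_b", "TG_b", "NEFA_b", "BW"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"SubjectSpec.{name} must be strictly positive, got {v}")

    @property
    def basal(self) -> dict[str, float]:
        return {"glucose": self.G_b, "insulin": self.I_b,
                "tg": self.TG_b, "nefa": self.NEFA_b}


@dataclass(frozen=True)
class MealSpec:
    """Ingested masses in grams.  Protein is carried for provenance but does
    not enter the dynamics (no protein/incretin effects in this model)."""

    G_meal: float = 75.0
    TG_meal: float = 60.0
    protein: float = 20.0

    def __post_init__(self) -> None:
        for name in ("G_meal", "TG_meal", "protein"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"MealSpec.{name} must be non-negative, got {v}")

    @property
    def G_mmol(self) -> float:
        return self.G_meal * 1000.0 / GLUCOSE_MOLAR_MASS

    @property
    def TG_mmol(self) -> float:
        return self.TG_meal * 1000.0 / TG_MOLAR_MASS


# standard study meals
NUTRITECH_MEAL = MealSpec(G_meal=75.0, TG_meal=60.0, protein=20.0)
METFLEX_MEAL = MealSpec(G_meal=67.0, TG_meal=36.0, protein=12.0)


@dataclass
class MealResponse:
    """Time-stamped measured plasma concentrations for up to four metabolites.

    Each metabolite has its own (possibly different, possibly sparser) sampling
    grid; missing samples are simply absent from the per-metabolite arrays.
    """

    times: dict[str, np.ndarray] = field(default_factory=dict)
    values: dict[str, np.ndarray] = field(default_factory=dict)
    subject: SubjectSpec = field(default_factory=SubjectSpec)
    meal: MealSpec = field(default_factory=MealSpec)

    def __post_init__(self) -> None:
        for m in self.times:
            if m not in METABOLITES:
                raise ValueError(f"unknown metabolite {m!r}")
            t = np.asarray(self.times[m], dtype=float)
            y = np.asarray(self.values[m], dtype=float)
            if t.shape != y.shape:
                raise ValueError(f"{m}: times and values differ in length")
            if t.size < 1:
                raise ValueError(f"{m}: at least one observation required")
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"{m}: times must be strictly increasing")
            if np.any(t < 0):
                raise ValueError(f"{m}: negative time")
            if np.any(~np.isfinite(y)) or np.any(y < 0):
                raise ValueError(f"{m}: observations must be finite and >= 0")
            self.times[m] = t
            self.values[m] = y

    @property
    def metabolites(self) -> tuple[str, ...]:
        return tuple(m for m in METABOLITES if m in self.times)
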