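"""The 13-state mixed-meal ODE system.

State vector (order fixed; total dimension 13):

====  ========  =======================================================
idx   name      meaning / units
====  ========  =======================================================
0     M_Ggut    glucose mass in the gut lumen, mmol
1     G_pl      plasma glucose, mmol/L
2     I_pl      plasma insulin, mU/L
3     I_d1      insulin delay chain stage 1 (= remote/interstitial
                insulin driving glucose uptake), mU/L
4     I_d2      delay chain stage 2, mU/L
5     I_d3      delay chain stage 3, mU/L
6     I_d4      delayed insulin signal acting on lipid fluxes, mU/L
7     E_int     integral state of the secretion controller, mmol*min/L
8     TG_g1     meal TG in gut/lymph transit stage 1, mmol
9     TG_g2     transit stage 2, mmol
10    TG_g3     transit stage 3, mmol
11    TG_pl     plasma triglyceride, mmol/L
12    NEFA_pl   plasma non-esterified fatty acids, mmol/L
====  ========  =======================================================

Glucose/insulin kinetics follow the E-DES family of oral-challenge models:
meal glucose is emptied from the stomach first-order (rate k1), transferred
to plasma from the gut lumen (rate k2, bioavailable fraction f_G), disposed
of by insulin-independent (Michaelis-Menten) and insulin-dependent routes,
and excreted renally above a threshold; insulin secretion is a
proportional-integral-derivative response to the glucose excursion, cleared
first-order and anchored at the fasting level.  Meal TG transits a
three-compartment gut/lymph cascade before appearing in plasma as
chylomicron TG; the liver secretes VLDL-TG at a rate suppressed by delayed
insulin (TG_liver = max(0, k16 - k15*(I_d4 - I_b))); LPL lipolysis clears
circulating TG in proportion to its concentration and increasing in delayed
insulin, and a fraction f_spill of the liberated fatty acids (three per TG
molecule) spills over into the plasma NEFA pool; adipose lipolysis releases
NEFA and is suppressed by delayed insulin.

The fasting state is made an exact equilibrium by `basal_closure`, which
derives the subject-specific basal fluxes (endogenous glucose production,
insulin-independent uptake, basal LPL activity, adipose release offset)
that balance the system at the measured fasting concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp

import numpy as np

from .parameters import ParameterSet
from .types import MealSpec, SubjectSpec

__all__ = [
    "N_STATES", "STATE_NAMES", "FLUX_NAMES", "BasalConstants", "FluxRecord",
    "basal_closure", "basal_state", "fluxes", "rhs", "BasalInfeasibleError",
    "BASAL_EGP", "MU_TO_PMOL", "pack_constants",
]

N_STATES = 13
STATE_NAMES = (
    "M_Ggut", "G_pl", "I_pl", "I_d1", "I_d2", "I_d3", "I_d4", "E_int",
    "TG_g1", "TG_g2", "TG_g3", "TG_pl", "NEFA_pl",
)

FLUX_NAMES = (
    "Ra_glucose", "EGP", "U_ii", "U_id", "U_ren",
    "Ra_TG", "TG_liver", "TG_LPL", "NEFA_ATL", "NEFA_uptake",
)

#: basal endogenous glucose production in concentration units, mmol/L/min
#: (~2 mg/kg/min at a nominal 0.17 L/kg glucose distribution volume).
BASAL_EGP = 0.065

#: unit conversion for the LPL insulin drive: k11 is tabulated per pmol/L of
#: insulin while the model tracks insulin in mU/L (1 mU/L = 6.945 pmol/L).
MU_TO_PMOL = 6.945


class BasalInfeasibleError(ValueError):
    """No non-negative basal flux balance exists for the given parameters and
    subject (e.g. spillover alone exceeds basal NEFA turnover)."""


@dataclass(frozen=True)
class BasalConstants:
    """Derived constants that close the fasting steady state.

    EGP_b      basal endogenous glucose production, mmol/L/min
    U_ii_b     basal insulin-independent glucose uptake, mmol/L/min
    c_lpl      basal (insulin-independent) LPL activity, 1/min
    atl_basal  total basal adipose NEFA release, mmol/L/min
    atl_offset non-suppressible part of adipose release, mmol/L/min
               (atl_basal = K_ATL + atl_offset)
    """

    EGP_b: float
    U_ii_b: float
    c_lpl: float
    atl_basal: float
    atl_offset: float


def basal_closure(params: ParameterSet, subject: SubjectSpec) -> BasalConstants:
    """Solve the fasting balance equations for the derived basal constants.

    With these constants the right-hand side evaluated at the basal state is
    identically zero, so a zero-meal simulation stays at the fasting values.

    Raises
    ------
    BasalInfeasibleError
        if any derived constant required to be non-negative is not, i.e. the
        measured fasting state cannot be an equilibrium of the model with the
        given parameters.
    """
    EGP_b = BASAL_EGP
    # glucose: Ra = 0, U_id = 0, U_ren = 0 at basal (G_b below the renal
    # threshold), so insulin-independent uptake balances EGP.
    U_ii_b = EGP_b
    if subject.G_b >= params["G_thresh"]:
        raise BasalInfeasibleError(
            "fasting glucose at/above the renal threshold: basal state cannot "
            "be closed with zero renal excretion"
        )
    # TG: at basal insulin the liver secretes k16; LPL must clear it at TG_b.
    c_lpl = (params["k16"] / subject.TG_b
             - params["k11"] * MU_TO_PMOL * subject.I_b)
    if c_lpl < 0:
        raise BasalInfeasibleError(
            "insulin-driven LPL flux alone exceeds basal hepatic TG secretion "
            "(k11*I_b*TG_b > k16): basal LPL activity would be negative"
        )
    # NEFA: adipose release + spillover (3 NEFA per TG) balances tissue uptake.
    atl_basal = params["k12"] * subject.NEFA_b - 3.0 * params["f_spill"] * params["k16"]
    if atl_basal <= 0:
        raise BasalInfeasibleError(
            "spillover alone exceeds basal NEFA turnover: adipose release "
            "would be non-positive at the fasting state"
        )
    atl_offset = atl_basal - params["K_ATL"]
    return BasalConstants(EGP_b=EGP_b, U_ii_b=U_ii_b, c_lpl=c_lpl,
                          atl_basal=atl_basal, atl_offset=atl_offset)


def basal_state(subject: SubjectSpec) -> np.ndarray:
    """The fasting state vector (no meal in transit, controller at rest)."""
    x = np.zeros(N_STATES)
    x[1] = subject.G_b
    x[2] = subject.I_b
    x[3:7] = subject.I_b
    x[11] = subject.TG_b
    x[12] = subject.NEFA_b
    return x


@dataclass(frozen=True)
class FluxRecord:
    """Named instantaneous fluxes (all in plasma-concentration units,
    mmol/L/min, for the compartment they feed)."""

    Ra_glucose: float
    EGP: float
    U_ii: float
    U_id: float
    U_ren: float
    Ra_TG: float
    TG_liver: float
    TG_LPL: float
    NEFA_ATL: float
    NEFA_uptake: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FLUX_NAMES])


def pack_constants(params: ParameterSet, subject: SubjectSpec, meal: MealSpec,
                   basal: BasalConstants | None = None) -> np.ndarray:
    """Flatten parameters, subject, meal and closure constants into one float
    vector consumed by the fast right-hand side (one dict traversal per
    simulation rather than one per integrator step)."""
    if basal is None:
        basal = basal_closure(params, subject)
    p = params.as_dict()
    return np.array([
        p["k1"], p["k2"], p["k3"], p["k4"], p["k5"], p["K_M"],          # 0-5
        p["k6"], p["k7"], p["k8"], p["k9"], p["k10"], p["G_thresh"],    # 6-11
        p["tau_i"], p["k11"], p["k12"], p["k13"], p["k14"], p["k15"],   # 12-17
        p["k16"], p["K_ATL"], p["c_ins"], p["f_spill"],                 # 18-21
        p["v_G"] * subject.BW, p["v_TG"] * subject.BW,                  # 22-23
        subject.G_b, subject.I_b, subject.TG_b, subject.NEFA_b,         # 24-27
        meal.G_mmol,                                                    # 28
        basal.EGP_b, basal.U_ii_b, basal.c_lpl, basal.atl_offset,       # 29-32
        p["f_G"],                                                       # 33
    ])


def _fluxes_c(x, c):
    """All ten named fluxes from state `x` (shape (13,) or (13, n)) and the
    packed constant vector `c`.  Uses numpy ufuncs so it vectorizes over a
    trajectory; `_rhs_c` is the scalar hot path (consistency is covered by a
    property test)."""
    G = x[1]
    I_d1 = x[3]
    I_d4 = x[6]
    Ra_glc = c[33] * c[1] * x[0] / c[22]
    EGP = np.maximum(0.0, c[29] - c[2] * (G - c[24]) - c[3] * (I_d1 - c[25]))
    mm = G / (c[5] + G)
    mm_b = c[24] / (c[5] + c[24])
    U_ii = c[30] * mm / mm_b
    U_id = c[4] * np.maximum(0.0, I_d1 - c[25]) / c[25] * mm
    U_ren = c[10] * np.maximum(0.0, G - c[11])
    Ra_TG = c[15] * x[10] / c[23]
    TG_liver = np.maximum(0.0, c[18] - c[17] * (I_d4 - c[25]))
    TG_LPL = (c[13] * MU_TO_PMOL * I_d4 + c[31]) * x[11]
    dI = np.maximum(0.0, I_d4 - c[25])
    NEFA_ATL = np.maximum(0.0, c[32] + c[19] / (1.0 + c[20] * dI))
    NEFA_uptake = c[14] * x[12]
    return (Ra_glc, EGP, U_ii, U_id, U_ren,
            Ra_TG, TG_liver, TG_LPL, NEFA_ATL, NEFA_uptake)


def _rhs_c(t, x, c):
    """Scalar-math right-hand side on the packed constant vector (hot path)."""
    M_Ggut = x[0] if x[0] > 0.0 else 0.0
    G = x[1] if x[1] > 0.0 else 0.0
    I_pl = x[2] if x[2] > 0.0 else 0.0
    I_d1 = x[3] if x[3] > 0.0 else 0.0
    I_d2 = x[4] if x[4] > 0.0 else 0.0
    I_d3 = x[5] if x[5] > 0.0 else 0.0
    I_d4 = x[6] if x[6] > 0.0 else 0.0
    E = x[7]
    TG_g1 = x[8] if x[8] > 0.0 else 0.0
    TG_g2 = x[9] if x[9] > 0.0 else 0.0
    TG_g3 = x[10] if x[10] > 0.0 else 0.0
    TG_pl = x[11] if x[11] > 0.0 else 0.0
    NEFA = x[12] if x[12] > 0.0 else 0.0

    G_b = c[24]
    I_b = c[25]

    Ra_glc = c[33] * c[1] * M_Ggut / c[22]
    EGP = c[29] - c[2] * (G - G_b) - c[3] * (I_d1 - I_b)
    if EGP < 0.0:
        EGP = 0.0
    mm = G / (c[5] + G)
    mm_b = G_b / (c[5] + G_b)
    U_ii = c[30] * mm / mm_b
    dI1 = I_d1 - I_b
    U_id = c[4] * (dI1 if dI1 > 0.0 else 0.0) / I_b * mm
    over = G - c[11]
    U_ren = c[10] * over if over > 0.0 else 0.0

    Ra_TG = c[15] * TG_g3 / c[23]
    TG_liver = c[18] - c[17] * (I_d4 - I_b)
    if TG_liver < 0.0:
        TG_liver = 0.0
    TG_LPL = (c[13] * MU_TO_PMOL * I_d4 + c[31]) * TG_pl
    dI4 = I_d4 - I_b
    if dI4 < 0.0:
        dI4 = 0.0
    NEFA_ATL = c[32] + c[19] / (1.0 + c[20] * dI4)
    if NEFA_ATL < 0.0:
        NEFA_ATL = 0.0

    dG = Ra_glc + EGP - U_ii - U_id - U_ren
    pid = c[6] * (G - G_b) + c[7] * E + c[8] * dG
    secretion = pid if pid > 0.0 else 0.0
    dE = (G - G_b) - E / c[12]
    if E <= 0.0 and dE < 0.0:
        dE = 0.0
    k13 = c[15]
    k14 = c[16]
    dx = np.empty(13)
    dx[0] = c[0] * c[28] * exp(-c[0] * t) - c[1] * M_Ggut
    dx[1] = dG
    dx[2] = secretion - c[9] * (I_pl - I_b)
    dx[3] = k14 * (I_pl - I_d1)
    dx[4] = k14 * (I_d1 - I_d2)
    dx[5] = k14 * (I_d2 - I_d3)
    dx[6] = k14 * (I_d3 - I_d4)
    dx[7] = dE
    dx[8] = -k13 * TG_g1
    dx[9] = k13 * (TG_g1 - TG_g2)
    dx[10] = k13 * (TG_g2 - TG_g3)
    dx[11] = Ra_TG + TG_liver - TG_LPL
    dx[12] = NEFA_ATL + 3.0 * c[21] * TG_LPL - c[14] * NEFA
    return dx


try:  # JIT the hot path when numba is present; pure-python fallback otherwise
    from numba import njit as _njit

    _rhs_c = _njit(cache=True)(_rhs_c)
except ImportError:  # pragma: no cover
    pass


def _check_state(state: np.ndarray) -> None:
    if state.shape[0] != N_STATES:
        raise ValueError(f"state must have length {N_STATES}, got {state.shape[0]}")
    if not np.all(np.isfinite(state)):
        raise ValueError("non-finite state")


def fluxes(t, state, params: ParameterSet, subject: SubjectSpec,
           meal: MealSpec, basal: BasalConstants | None = None) -> FluxRecord:
    """Evaluate all named instantaneous fluxes at one time point."""
    state = np.asarray(state, dtype=float)
    _check_state(state)
    c = pack_constants(params, subject, meal, basal)
    vals = _fluxes_c(np.maximum(state, 0.0), c)
    return FluxRecord(*(float(v) for v in vals))


def rhs(t: float, state: np.ndarray, params: ParameterSet,
        subject: SubjectSpec, meal: MealSpec,
        basal: BasalConstants | None = None) -> np.ndarray:
    """Time-derivative of the 13-state system at time t (minutes)."""
    if t < 0:
        raise ValueError("t must be >= 0")
    state = np.asarray(state, dtype=float)
    _check_state(state)
    c = pack_constants(params, subject, meal, basal)
    return _rhs_c(float(t), state, c)
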