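"""Temperature- and time-dependent rate functions for the whitefly life cycle.

Every biodemographic response used by the cohort engine lives here as a pure
function: development rate r(T) per immature stage, immature mortality m(T),
daily survival S(T), adult oviposition rate phi(T), lifetime fecundity
capacity psi(T), adult senescence rate, crop-suitability decline CS(t) and the
density-dependent nymph survival sD = 1/(1 + K*Nn).

Functional forms are looked up in a registry keyed by name, so alternative
parametrisations (e.g. lab-calibrated curves for a particular biotype) can be
dropped in through configuration without touching the engine.  The shipped
defaults are literature-standard shapes (Briere-1 development, quadratic
mortality bowl, Gaussian capacity) with placeholder parameter values — they
produce realistic tropical whitefly dynamics but are not calibrated to any
particular laboratory dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Sequence, Tuple

import numpy as np

# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

IMMATURE_STAGES = ("egg", "nymph", "pupa")


@dataclass(frozen=True)
class StageParams:
    """Thermal parameters of one immature stage.

    TL/TU are the lower/upper developmental thresholds in °C: development is
    exactly zero at and outside [TL, TU].  ``dev_form``/``mort_form`` name
    entries in the rate-function registry; ``dev_params``/``mort_params`` are
    their parameter vectors.
    """

    stage_name: str
    TL: float
    TU: float
    dev_form: str = "briere1"
    dev_params: Tuple[float, ...] = ()
    mort_form: str = "quadratic"
    mort_params: Tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.stage_name not in IMMATURE_STAGES:
            raise ValueError(f"unknown immature stage {self.stage_name!r}")
        if not self.TL < self.TU:
            raise ValueError(
                f"{self.stage_name}: lower threshold TL={self.TL} must be "
                f"below upper threshold TU={self.TU}")


@dataclass(frozen=True)
class AdultParams:
    """Adult reproduction and senescence parameters.

    ``sex_ratio`` is the fraction of females (default 0.5).  Egg production
    is restricted to ``repro_T_range`` (default 4–36 °C); outside it the
    oviposition rate is zero.
    """

    sex_ratio: float = 0.5
    repro_T_range: Tuple[float, float] = (4.0, 36.0)
    ovi_form: str = "briere1"
    ovi_params: Tuple[float, ...] = ()
    cap_form: str = "gaussian"
    cap_params: Tuple[float, ...] = ()
    sen_form: str = "linear"
    sen_params: Tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must be in [0, 1]")
        lo, hi = self.repro_T_range
        if not lo < hi:
            raise ValueError("repro_T_range must be (low, high) with low < high")


@dataclass(frozen=True)
class LethalLimits:
    """Lower/upper lethal temperatures: daily survival is 0 at and beyond them."""

    LLT: float = 4.0
    ULT: float = 36.0

    def __post_init__(self) -> None:
        if not self.LLT < self.ULT:
            raise ValueError("LLT must be below ULT")


@dataclass(frozen=True)
class CropParams:
    """Host-crop effects: suitability decline CS(t) and crowding strength K."""

    K: float = 0.01
    cs_form: str = "hill"
    cs_params: Tuple[float, ...] = (90.0, 4.0)  # (t_half days, shape)

    def __post_init__(self) -> None:
        if self.K < 0:
            raise ValueError("density-dependence strength K must be >= 0")


# ---------------------------------------------------------------------------
# rate-function registry
# ---------------------------------------------------------------------------

def _briere1(T, lo: float, hi: float, a: float):
    """Briere-1 rate a*T*(T-lo)*sqrt(hi-T) inside (lo, hi), else 0."""
    T = np.asarray(T, dtype=float)
    inside = (T > lo) & (T < hi)
    r = np.zeros_like(T)
    Ti = T[inside]
    r[inside] = a * Ti * (Ti - lo) * np.sqrt(hi - Ti)
    return np.maximum(r, 0.0)


def _quadratic_mortality(T, m_min: float, T_opt: float, curv: float):
    """Mortality bowl m_min + curv*(T-T_opt)^2, clipped to [0, 1]."""
    T = np.asarray(T, dtype=float)
    return np.clip(m_min + curv * (T - T_opt) ** 2, 0.0, 1.0)


def _gaussian(T, peak: float, T_opt: float, sigma: float):
    T = np.asarray(T, dtype=float)
    return peak * np.exp(-0.5 * ((T - T_opt) / sigma) ** 2)


def _linear_rate(T, a: float, b: float):
    """Non-negative linear rate max(0, a + b*T)."""
    T = np.asarray(T, dtype=float)
    return np.maximum(a + b * T, 0.0)


def _hill_decline(t, t_half: float, shape: float):
    """Suitability 1/(1+(t/t_half)^shape): 1 at t=0, 0.5 at t=t_half."""
    t = np.asarray(t, dtype=float)
    return 1.0 / (1.0 + (t / t_half) ** shape)


#: registry of named rate forms; each maps (x, *params) -> ndarray
RATE_FORMS: Dict[str, Callable] = {
    "briere1": _briere1,
    "quadratic": _quadratic_mortality,
    "gaussian": _gaussian,
    "linear": _linear_rate,
    "hill": _hill_decline,
}


def register_rate_form(name: str, fn: Callable) -> None:
    """Register a custom rate form under ``name`` (overwrites existing)."""
    RATE_FORMS[name] = fn


def _as_scalar_or_array(x, arr):
    return float(arr) if np.isscalar(x) else arr


# ---------------------------------------------------------------------------
# stage responses
# ---------------------------------------------------------------------------

def development_rate(T, params: StageParams):
    """Per-day development fraction r(T) for an immature stage.

    Zero at and outside the permissive range [TL, TU], continuous inside.
    Accepts scalars or arrays of °C.
    """
    fn = RATE_FORMS[params.dev_form]
    if params.dev_form == "briere1":
        r = fn(T, params.TL, params.TU, *params.dev_params)
    else:
        r = fn(T, *params.dev_params)
        r = np.where(
            (np.asarray(T, float) <= params.TL) | (np.asarray(T, float) >= params.TU),
            0.0, r)
    return _as_scalar_or_array(T, r)


def mortality_rate(T, params: StageParams):
    """Daily immature mortality probability m(T), clipped to [0, 1]."""
    m = RATE_FORMS[params.mort_form](T, *params.mort_params)
    return _as_scalar_or_array(T, np.clip(m, 0.0, 1.0))


def daily_survival(T, params: StageParams, lethal: LethalLimits,
                   mode: str = "power"):
    """Daily survival probability of an immature stage.

    Inside the lethal range (LLT, ULT) the default reading raises stage
    survival to the day's development fraction, S = (1-m)^r, so a day of zero
    development contributes no development-weighted mortality (S = 1).  The
    alternative ``mode="product"`` reads the expression multiplicatively,
    S = clip((1-m)*r, 0, 1).  At or beyond the lethal limits S = 0.
    """
    T_arr = np.asarray(T, dtype=float)
    m = np.clip(RATE_FORMS[params.mort_form](T_arr, *params.mort_params), 0.0, 1.0)
    r = np.asarray(development_rate(T_arr, params), dtype=float)
    if mode == "power":
        S = np.power(1.0 - m, r)
    elif mode == "product":
        S = np.clip((1.0 - m) * r, 0.0, 1.0)
    else:
        raise ValueError(f"unknown survival mode {mode!r}")
    S = np.where((T_arr <= lethal.LLT) | (T_arr >= lethal.ULT), 0.0, S)
    return _as_scalar_or_array(T, S)


# ---------------------------------------------------------------------------
# adult responses
# ---------------------------------------------------------------------------

def oviposition_rate(T, params: AdultParams):
    """Daily fraction phi(T) of lifetime egg output realised; 0 outside the
    reproductive temperature range.  Accumulating phi to 1 ends fecundity."""
    lo, hi = params.repro_T_range
    fn = RATE_FORMS[params.ovi_form]
    if params.ovi_form == "briere1":
        phi = fn(T, lo, hi, *params.ovi_params)
    else:
        phi = np.asarray(fn(T, *params.ovi_params), dtype=float)
        T_arr = np.asarray(T, dtype=float)
        phi = np.where((T_arr <= lo) | (T_arr >= hi), 0.0, phi)
    return _as_scalar_or_array(T, np.maximum(phi, 0.0))


def fecundity_capacity(T, params: AdultParams):
    """Lifetime egg capacity psi(T) (eggs per female), single-peaked in T."""
    psi = RATE_FORMS[params.cap_form](T, *params.cap_params)
    return _as_scalar_or_array(T, np.maximum(psi, 0.0))


def senescence_rate(T, params: AdultParams):
    """Post-reproductive ageing rate; accumulation to 1 kills the cohort."""
    s = RATE_FORMS[params.sen_form](T, *params.sen_params)
    return _as_scalar_or_array(T, np.maximum(s, 0.0))


# ---------------------------------------------------------------------------
# crop and density effects
# ---------------------------------------------------------------------------

def crop_suitability(t, params: CropParams):
    """Crop suitability CS(t) in [0, 1] for crop age t (days since planting);
    CS(0) = 1 and CS is non-increasing in t."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("crop age t must be >= 0")
    cs = np.clip(RATE_FORMS[params.cs_form](t_arr, *params.cs_params), 0.0, 1.0)
    return _as_scalar_or_array(t, cs)


def density_survival(Nn, K: float):
    """Crowding survival sD = 1/(1 + K*Nn) applied to nymphs."""
    Nn_arr = np.asarray(Nn, dtype=float)
    if np.any(Nn_arr < 0):
        raise ValueError("nymph count Nn must be >= 0")
    if K < 0:
        raise ValueError("K must be >= 0")
    return _as_scalar_or_array(Nn, 1.0 / (1.0 + K * Nn_arr))


# ---------------------------------------------------------------------------
# placeholder default parameter set (not lab-calibrated)
# ---------------------------------------------------------------------------

def default_stage_params() -> Dict[str, StageParams]:
    """Placeholder thermal parameters for a tropical whitefly on cassava.

    Chosen to give stage durations near 7 (egg), 13 (nymph) and 6 ('pupa')
    days at 26 °C with thresholds 10–35 °C; NOT calibrated to any appendix
    or laboratory dataset.
    """
    return {
        "egg": StageParams("egg", TL=10.0, TU=35.0,
                           dev_params=(1.1e-4,),
                           mort_params=(0.02, 27.0, 0.001)),
        "nymph": StageParams("nymph", TL=10.0, TU=35.0,
                             dev_params=(5.5e-5,),
                             mort_params=(0.02, 27.0, 0.001)),
        "pupa": StageParams("pupa", TL=10.0, TU=35.0,
                            dev_params=(1.3e-4,),
                            mort_params=(0.02, 27.0, 0.001)),
    }


def default_adult_params() -> AdultParams:
    """Placeholder adult parameters: ~12-day fecund period and ~150-egg
    lifetime capacity near the 27 °C optimum."""
    return AdultParams(
        sex_ratio=0.5,
        repro_T_range=(4.0, 36.0),
        ovi_params=(4.4e-5,),
        cap_params=(160.0, 27.0, 6.0),
        sen_params=(-0.018, 0.0045),
    )
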