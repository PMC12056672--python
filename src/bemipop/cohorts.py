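"""Daily-step stage-structured cohort bookkeeping.

The population is a collection of cohorts — same-aged groups within one life
stage (egg, nymph, 'pupa', reproductive adult, post-reproductive adult).
Each simulated day applies, in this fixed order:

1. survival: immature cohort sizes shrink by the stage's daily survival
   S(T); nymphs additionally by the crowding factor sD = 1/(1+K*Nn) and the
   crop-suitability multiplier CS(crop age);
2. ageing: immature physiological age Q advances by r(T)*dt (dt = 1 day),
   only when T lies strictly inside the permissive range (TL, TU);
3. transitions: cohorts reaching Q >= 1 move their whole surviving size to
   the next stage at age 0 ('pupa' -> reproductive adult with a fresh
   fecundity accumulator); overshoot above 1 is discarded;
4. reproduction: all reproductive adults lay one aggregate new egg cohort of
   size f = SR * phi(T) * psi(T) * N_A;
5. adult accounting: the fecundity accumulator advances by phi(T); adults
   completing it become post-reproductive; the senescence accumulator then
   advances and senesced cohorts die;
6. cohorts smaller than the extinction threshold are removed.

Mortality acts on the population that existed at the day's start, and eggs
laid today cannot age today — this motivates the order above.  Cohort sizes
are continuous densities (multiplicative daily survival), not integers.
Adults carry no background temperature mortality by default; they die only
through completed senescence (a lethal-limit kill switch for adults exists
in the config and is off by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .thermal import (AdultParams, CropParams, LethalLimits, StageParams,
                      crop_suitability, daily_survival, default_adult_params,
                      default_stage_params, density_survival,
                      development_rate, fecundity_capacity, oviposition_rate,
                      senescence_rate)

# stage codes (array representation)
EGG, NYMPH, PUPA, ADULT_REPRO, ADULT_POST = 0, 1, 2, 3, 4
STAGE_NAMES = ("egg", "nymph", "pupa", "adult_repro", "adult_post")
_IMMATURE_CODES = (EGG, NYMPH, PUPA)

MAX_INITIAL_SIZE = 1e6
MAX_INITIAL_AGE = 0.99

#: accumulator completion tolerance: sums of daily rate increments meant to
#: reach exactly 1 (e.g. 10 x 0.1) can undershoot by float rounding
ACC_EPS = 1e-9
_ACC_THRESHOLD = 1.0 - ACC_EPS


@dataclass(frozen=True)
class EngineConfig:
    """Everything the daily update needs: thermal parameters per stage,
    adult parameters, lethal limits, crop/density effects and numerical
    switches."""

    stage_params: Dict[str, StageParams] = field(default_factory=default_stage_params)
    adult_params: AdultParams = field(default_factory=default_adult_params)
    lethal: LethalLimits = field(default_factory=LethalLimits)
    crop: CropParams = field(default_factory=CropParams)
    survival_mode: str = "power"        # "power": S=(1-m)^r; "product": S=(1-m)*r
    adult_lethal_kill: bool = False     # kill adults outside (LLT, ULT)?
    planting_offset: int = 17           # day 0 is this many days after planting
    extinction_eps: float = 1e-6        # cohorts below this size are removed

    def with_K(self, K: float) -> "EngineConfig":
        return replace(self, crop=replace(self.crop, K=K))


@dataclass
class Cohort:
    """One same-aged group: stage, size (individuals, real-valued), and the
    accumulator relevant to its stage (physiological age Q for immatures,
    fecundity/senescence integrals for adults)."""

    stage: str
    size: float
    age: float = 0.0
    fec_acc: float = 0.0
    sen_acc: float = 0.0
    birth_day: int = 0


@dataclass(frozen=True)
class InitialConditions:
    """Initial cohort sizes and physiological ages at day 0 (= first
    monitoring date t1).  One cohort per non-empty immature stage; an
    optional initial adult population starts reproductive at fec_acc 0."""

    egg_size: float = 0.0
    nymph_size: float = 0.0
    pupa_size: float = 0.0
    egg_age: float = 0.0
    nymph_age: float = 0.0
    pupa_age: float = 0.0
    adult_size: float = 0.0

    def __post_init__(self) -> None:
        for name in ("egg_size", "nymph_size", "pupa_size", "adult_size"):
            v = getattr(self, name)
            if not 0.0 <= v <= MAX_INITIAL_SIZE:
                raise ValueError(f"{name}={v} outside [0, {MAX_INITIAL_SIZE:g}]")
        for name in ("egg_age", "nymph_age", "pupa_age"):
            v = getattr(self, name)
            if not 0.0 <= v <= MAX_INITIAL_AGE:
                raise ValueError(f"{name}={v} outside [0, {MAX_INITIAL_AGE}]")

    def size_of(self, stage: str) -> float:
        return getattr(self, f"{stage}_size")

    def age_of(self, stage: str) -> float:
        return getattr(self, f"{stage}_age")


class PopulationState:
    """All live cohorts plus the current simulation day.

    Cohorts are stored as parallel numpy arrays for speed; ``cohorts()``
    materialises them as :class:`Cohort` objects.
    """

    __slots__ = ("stage", "size", "age", "fec", "sen", "birth", "day",
                 "day0_date")

    def __init__(self, day0_date=None):
        self.stage = np.empty(0, dtype=np.int64)
        self.size = np.empty(0, dtype=float)
        self.age = np.empty(0, dtype=float)
        self.fec = np.empty(0, dtype=float)
        self.sen = np.empty(0, dtype=float)
        self.birth = np.empty(0, dtype=np.int64)
        self.day = 0
        self.day0_date = pd.Timestamp(day0_date).normalize() if day0_date is not None else None

    def copy(self) -> "PopulationState":
        new = PopulationState(self.day0_date)
        for name in ("stage", "size", "age", "fec", "sen", "birth"):
            setattr(new, name, getattr(self, name).copy())
        new.day = self.day
        return new

    def add_cohort(self, stage_code: int, size: float, age: float = 0.0,
                   fec: float = 0.0, sen: float = 0.0,
                   birth_day: Optional[int] = None) -> None:
        self.stage = np.append(self.stage, stage_code)
        self.size = np.append(self.size, size)
        self.age = np.append(self.age, age)
        self.fec = np.append(self.fec, fec)
        self.sen = np.append(self.sen, sen)
        self.birth = np.append(self.birth, self.day if birth_day is None else birth_day)

    def stage_total(self, stage_code: int) -> float:
        return float(self.size[self.stage == stage_code].sum())

    def totals(self) -> np.ndarray:
        """Sizes summed per stage code, in STAGE_NAMES order."""
        out = np.zeros(len(STAGE_NAMES))
        np.add.at(out, self.stage, self.size)
        return out

    def cohorts(self):
        return [Cohort(STAGE_NAMES[s], float(z), float(a), float(f), float(q), int(b))
                for s, z, a, f, q, b in
                zip(self.stage, self.size, self.age, self.fec, self.sen, self.birth)]

    @property
    def n_cohorts(self) -> int:
        return len(self.size)


@dataclass(frozen=True)
class StageSeries:
    """Daily stage totals aligned to the simulation day index; totals are
    recorded at the start of each day, before that day's update, so day 0
    equals the initial conditions."""

    dates: pd.DatetimeIndex
    table: np.ndarray  # shape (n_days, 5), columns in STAGE_NAMES order

    def __post_init__(self) -> None:
        if self.table.shape != (len(self.dates), len(STAGE_NAMES)):
            raise ValueError("table shape does not match dates/stages")

    def column(self, stage: str) -> np.ndarray:
        if stage == "adult" or stage == "adult_total":
            return self.table[:, ADULT_REPRO] + self.table[:, ADULT_POST]
        return self.table[:, STAGE_NAMES.index(stage)]

    def total_on(self, date, stage: str) -> float:
        date = pd.Timestamp(date).normalize()
        i = (date - self.dates[0]) // pd.Timedelta(days=1)
        if i < 0 or i >= len(self.dates):
            raise KeyError(f"date {date.date()} outside simulated horizon "
                           f"[{self.dates[0].date()}, {self.dates[-1].date()}]")
        return float(self.column(stage)[int(i)])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.table, columns=list(STAGE_NAMES))
        df.insert(0, "day_index", np.arange(len(self.dates)))
        df.insert(0, "date", self.dates)
        df["adult_total"] = df["adult_repro"] + df["adult_post"]
        return df


# ---------------------------------------------------------------------------
# engine
# ---------------------------------------------------------------------------

def init_state(ic: InitialConditions, day0_date) -> PopulationState:
    """Build the day-0 state: one cohort per non-empty stage."""
    state = PopulationState(day0_date)
    for code, stage in zip(_IMMATURE_CODES, ("egg", "nymph", "pupa")):
        size = ic.size_of(stage)
        if size > 0:
            state.add_cohort(code, size, age=ic.age_of(stage))
    if ic.adult_size > 0:
        state.add_cohort(ADULT_REPRO, ic.adult_size)
    return state


def _step_inplace(state: PopulationState, T: float, cfg: EngineConfig) -> None:
    if not np.isfinite(T):
        raise ValueError(f"non-finite temperature {T!r} on day {state.day}")
    stage, size, age = state.stage, state.size, state.age
    sp = cfg.stage_params
    lethal = cfg.lethal

    if len(size):
        # (1) survival of immatures; nymphs get the crowding and crop factors
        nymph_mask = stage == NYMPH
        Nn = float(size[nymph_mask].sum())
        sD = density_survival(Nn, cfg.crop.K)
        CS = crop_suitability(state.day + cfg.planting_offset, cfg.crop)
        for code, name in zip(_IMMATURE_CODES, ("egg", "nymph", "pupa")):
            mask = stage == code
            if not mask.any():
                continue
            S = daily_survival(T, sp[name], lethal, mode=cfg.survival_mode)
            if code == NYMPH:
                S *= sD * CS
            size[mask] *= S
        if cfg.adult_lethal_kill and (T <= lethal.LLT or T >= lethal.ULT):
            size[stage >= ADULT_REPRO] = 0.0

        # (2) ageing of immatures (rate is 0 outside the permissive range)
        for code, name in zip(_IMMATURE_CODES, ("egg", "nymph", "pupa")):
            mask = stage == code
            if mask.any():
                age[mask] += development_rate(T, sp[name])

        # (3) transitions at Q >= 1; overshoot discarded, next stage starts at 0
        done = (stage <= PUPA) & (age >= _ACC_THRESHOLD) & (size > 0)
        if done.any():
            stage[done] += 1
            age[done] = 0.0
            state.fec[done] = 0.0  # fresh adults start their fecund period

    # (4) reproduction: one aggregate egg cohort from all reproductive adults
    ap = cfg.adult_params
    repro = state.stage == ADULT_REPRO
    N_A = float(state.size[repro].sum())
    if N_A > 0:
        f = ap.sex_ratio * oviposition_rate(T, ap) * fecundity_capacity(T, ap) * N_A
        if f > 0:
            state.add_cohort(EGG, f, age=0.0)
            repro = state.stage == ADULT_REPRO  # arrays were reallocated

    # (5) adult accumulators: fecundity, then senescence
    phi = oviposition_rate(T, ap)
    state.fec[repro] += phi
    finished = repro & (state.fec >= _ACC_THRESHOLD)
    if finished.any():
        state.stage[finished] = ADULT_POST
        state.sen[finished] = 0.0
    post = state.stage == ADULT_POST
    if post.any():
        state.sen[post] += senescence_rate(T, ap)
        state.size[post & (state.sen >= _ACC_THRESHOLD)] = 0.0

    # (6) remove extinct cohorts; (7) advance the day
    keep = state.size >= cfg.extinction_eps
    if not keep.all():
        for name in ("stage", "size", "age", "fec", "sen", "birth"):
            setattr(state, name, getattr(state, name)[keep])
    state.day += 1


def step_day(state: PopulationState, T: float, cfg: EngineConfig) -> PopulationState:
    """One day's update (functional: returns a new state)."""
    new = state.copy()
    _step_inplace(new, float(T), cfg)
    return new


@dataclass(frozen=True)
class DailyRates:
    """Per-day thermal responses precomputed for a fixed temperature window.

    None of these depend on the initial conditions or on K, so one table
    serves every candidate vector during fitting."""

    surv: np.ndarray            # (n_days, 3) immature daily survival S_i
    dev: np.ndarray             # (n_days, 3) development rates r_i
    phi: np.ndarray             # (n_days,) oviposition rate
    eggs_per_adult: np.ndarray  # (n_days,) SR * phi * psi
    sen: np.ndarray             # (n_days,) senescence rate
    cs: np.ndarray              # (n_days,) crop suitability at day's crop age
    adult_kill: np.ndarray      # (n_days,) bool, lethal kill applies to adults


def precompute_rates(T_seq: np.ndarray, cfg: EngineConfig) -> DailyRates:
    """Evaluate every temperature-dependent response for a day-0-aligned
    temperature window (used by :func:`simulate`'s fast path)."""
    T_seq = np.asarray(T_seq, dtype=float)
    if not np.all(np.isfinite(T_seq)):
        raise ValueError("non-finite temperature in simulation window")
    n = len(T_seq)
    surv = np.empty((n, 3))
    dev = np.empty((n, 3))
    for j, name in enumerate(("egg", "nymph", "pupa")):
        sp = cfg.stage_params[name]
        surv[:, j] = daily_survival(T_seq, sp, cfg.lethal, mode=cfg.survival_mode)
        dev[:, j] = development_rate(T_seq, sp)
    ap = cfg.adult_params
    phi = np.asarray(oviposition_rate(T_seq, ap), dtype=float)
    eggs_per_adult = ap.sex_ratio * phi * np.asarray(
        fecundity_capacity(T_seq, ap), dtype=float)
    sen = np.asarray(senescence_rate(T_seq, ap), dtype=float)
    crop_age = np.arange(n, dtype=float) + cfg.planting_offset
    cs = np.asarray(crop_suitability(crop_age, cfg.crop), dtype=float)
    if cfg.adult_lethal_kill:
        adult_kill = (T_seq <= cfg.lethal.LLT) | (T_seq >= cfg.lethal.ULT)
    else:
        adult_kill = np.zeros(n, dtype=bool)
    return DailyRates(surv=surv, dev=dev, phi=phi,
                      eggs_per_adult=eggs_per_adult, sen=sen, cs=cs,
                      adult_kill=adult_kill)


def _run_fast(ic: InitialConditions, rates: DailyRates, cfg: EngineConfig,
              n_days: int) -> np.ndarray:
    """Daily loop on preallocated arrays; semantics identical to repeated
    :func:`step_day` (asserted by the test suite)."""
    cap = 8 + n_days  # <= one new egg cohort per day
    stage = np.zeros(cap, dtype=np.int64)
    size = np.zeros(cap)
    age = np.zeros(cap)
    fec = np.zeros(cap)
    sen = np.zeros(cap)
    m = 0
    for code, name in zip(_IMMATURE_CODES, ("egg", "nymph", "pupa")):
        if ic.size_of(name) > 0:
            stage[m], size[m], age[m] = code, ic.size_of(name), ic.age_of(name)
            m += 1
    if ic.adult_size > 0:
        stage[m], size[m] = ADULT_REPRO, ic.adult_size
        m += 1

    K = cfg.crop.K
    eps = cfg.extinction_eps
    table = np.zeros((n_days, len(STAGE_NAMES)))
    fac = np.ones(len(STAGE_NAMES))
    inc = np.zeros(len(STAGE_NAMES))
    for d in range(n_days):
        st, sz, ag = stage[:m], size[:m], age[:m]
        tot = np.bincount(st, weights=sz, minlength=len(STAGE_NAMES))
        table[d] = tot
        if m:
            # (1) survival (nymphs also crowding sD and crop suitability CS)
            sD = 1.0 / (1.0 + K * tot[NYMPH])
            fac[:3] = rates.surv[d]
            fac[NYMPH] = fac[NYMPH] * (sD * rates.cs[d])
            fac[3:] = 0.0 if rates.adult_kill[d] else 1.0
            sz *= fac[st]
            # (2) ageing
            inc[:3] = rates.dev[d]
            ag += inc[st]
            # (3) transitions at Q >= 1
            done = (st <= PUPA) & (ag >= _ACC_THRESHOLD) & (sz > 0)
            if done.any():
                st[done] += 1
                ag[done] = 0.0
                fec[:m][done] = 0.0
        # (4) reproduction
        repro = stage[:m] == ADULT_REPRO
        N_A = size[:m][repro].sum()
        if N_A > 0:
            f = rates.eggs_per_adult[d] * N_A
            if f > 0:
                stage[m], size[m], age[m], fec[m], sen[m] = EGG, f, 0.0, 0.0, 0.0
                m += 1
        # (5) adult accumulators
        if repro.any():
            fk = fec[:len(repro)]
            fk[repro] += rates.phi[d]
            finished = repro & (fk >= _ACC_THRESHOLD)
            if finished.any():
                stage[:len(repro)][finished] = ADULT_POST
                sen[:len(repro)][finished] = 0.0
        post = stage[:m] == ADULT_POST
        if post.any():
            sk = sen[:m]
            sk[post] += rates.sen[d]
            size[:m][post & (sk >= _ACC_THRESHOLD)] = 0.0
        # (6) removal
        dead = size[:m] < eps
        if dead.any():
            keep = ~dead
            k = int(keep.sum())
            for arr in (stage, size, age, fec, sen):
                arr[:k] = arr[:m][keep]
            m = k
    return table


def simulate(ic: InitialConditions, temps, cfg: EngineConfig,
             start_date=None, n_days: Optional[int] = None,
             rates: Optional[DailyRates] = None) -> StageSeries:
    """Run the engine for ``n_days`` from ``start_date`` and record daily
    stage totals (taken at the start of each day, before its update).

    ``temps`` is a :class:`~bemipop.timeseries.TemperatureSeries` covering
    the whole horizon; a missing day raises an error naming the date.
    ``rates`` may carry a precomputed :class:`DailyRates` table for the same
    window (the fitting objective reuses one table across candidates).
    """
    start = pd.Timestamp(start_date).normalize() if start_date is not None else temps.start
    if n_days is None:
        n_days = int((temps.end - start) // pd.Timedelta(days=1)) + 1
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    T_seq = temps.window(start, n_days)
    if rates is None:
        rates = precompute_rates(T_seq, cfg)
    table = _run_fast(ic, rates, cfg, n_days)
    dates = pd.date_range(start, periods=n_days, freq="D")
    return StageSeries(dates=dates, table=table)
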