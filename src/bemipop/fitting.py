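"""Estimation of initial cohort sizes, initial physiological ages and the
density-dependence strength K from trap-monitoring data.

The estimator wraps a classic differential-evolution search (DE/rand/1/bin)
around the forward cohort simulation: each candidate vector of initial
conditions is simulated over the monitoring horizon and scored by the
residual sum of squares between observed and simulated counts at the
sampling dates,

    RSS = sum_k (O_k - S_k)^2,   k = 1..Omega,

matching each observation to the simulated total of its stage on its exact
calendar date (no interpolation; a date outside the simulated horizon is a
hard error).  Adult and nymph records enter the pooled sum unweighted by
default; per-stage weights are available.

Two estimation arms are supported: ``free_age`` searches
(size_egg, size_nymph, size_pupa, r0_egg, r0_nymph, r0_pupa, K), while
``zero_age`` pins the three initial ages at 0 and searches only the sizes
and K — the conventional assumption that no thermal history preceded the
first trap visit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cohorts import (EngineConfig, InitialConditions, StageSeries,
                      precompute_rates, simulate)
from .timeseries import MonitoringSeries, TemperatureSeries

_STAGE_TO_COLUMN = {"adult": "adult_total", "nymph": "nymph"}

#: default search box per estimated quantity
DEFAULT_BOUNDS: Dict[str, Tuple[float, float]] = {
    "egg_size": (0.0, 1e6),
    "nymph_size": (0.0, 1e6),
    "pupa_size": (0.0, 1e6),
    "egg_age": (0.0, 0.99),
    "nymph_age": (0.0, 0.99),
    "pupa_age": (0.0, 0.99),
    "K": (1e-5, 1e2),
}

FREE_AGE_NAMES = ("egg_size", "nymph_size", "pupa_size",
                  "egg_age", "nymph_age", "pupa_age", "K")
ZERO_AGE_NAMES = ("egg_size", "nymph_size", "pupa_size", "K")


def rss(observed: MonitoringSeries, simulated: StageSeries,
        weights: Optional[Dict[str, float]] = None) -> float:
    """Pooled residual sum of squares between observed counts and the
    simulated stage totals at the observation dates."""
    total = 0.0
    for row in observed.records.itertuples(index=False):
        col = _STAGE_TO_COLUMN[row.stage]
        s_k = simulated.total_on(row.date, col)
        w = 1.0 if weights is None else weights.get(row.stage, 1.0)
        total += w * (row.count - s_k) ** 2
    return float(total)


# ---------------------------------------------------------------------------
# differential evolution (DE/rand/1/bin)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DESettings:
    """Differential-evolution hyperparameters.

    ``pop_size`` defaults to 10x the problem dimension (canonical
    Storn-Price sizing); mutation needs three distinct partners plus the
    target, so at least 4 members are required.  The search stops when the
    best RSS improves by less than ``tol`` (relative) over ``patience``
    consecutive generations, or at ``max_generations``.
    """

    pop_size: Optional[int] = None
    F: float = 0.8
    CR: float = 0.9
    max_generations: int = 500
    tol: float = 1e-8
    patience: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.F <= 2.0:
            raise ValueError("F must be in (0, 2]")
        if not 0.0 <= self.CR <= 1.0:
            raise ValueError("CR must be in [0, 1]")
        if self.pop_size is not None and self.pop_size < 4:
            raise ValueError("pop_size must be >= 4 (3 partners + target)")

    def resolved_pop_size(self, dim: int) -> int:
        n = self.pop_size if self.pop_size is not None else 10 * dim
        if n < 4:
            raise ValueError("pop_size must be >= 4 (3 partners + target)")
        return n


@dataclass
class DEResult:
    """Outcome of one DE run."""

    x: np.ndarray
    fun: float
    trace: np.ndarray          # per-generation best objective value
    generations: int
    converged: bool
    seed: int


def de_minimize(objective: Callable[[np.ndarray], float],
                bounds: Sequence[Tuple[float, float]],
                settings: DESettings,
                init: Optional[np.ndarray] = None) -> DEResult:
    """Minimise ``objective`` on a bounded box with DE/rand/1/bin.

    Uniform random initialisation inside the bounds (rows of ``init``, if
    given, overwrite the first members — useful to seed a known feasible
    point); mutant v = x_r1 + F*(x_r2 - x_r3) with distinct random partners;
    binomial crossover with one guaranteed mutant coordinate; out-of-bounds
    coordinates clipped to the box; greedy selection.  Fully reproducible
    for a given seed.
    """
    lo = np.asarray([b[0] for b in bounds], dtype=float)
    hi = np.asarray([b[1] for b in bounds], dtype=float)
    if np.any(lo >= hi):
        bad = int(np.argmax(lo >= hi))
        raise ValueError(f"bounds[{bad}]=({lo[bad]}, {hi[bad]}) needs low < high")
    dim = len(lo)
    NP = settings.resolved_pop_size(dim)

    rng = np.random.default_rng(settings.seed)
    pop = lo + rng.random((NP, dim)) * (hi - lo)
    if init is not None:
        init = np.atleast_2d(np.asarray(init, dtype=float))
        k = min(len(init), NP)
        pop[:k] = np.clip(init[:k], lo, hi)
    fitness = np.array([objective(x) for x in pop], dtype=float)

    trace = []
    best_idx = int(np.argmin(fitness))
    gen = 0
    converged = False
    for gen in range(1, settings.max_generations + 1):
        for i in range(NP):
            r1, r2, r3 = _distinct_partners(rng, NP, i)
            mutant = np.clip(pop[r1] + settings.F * (pop[r2] - pop[r3]), lo, hi)
            cross = rng.random(dim) < settings.CR
            cross[rng.integers(dim)] = True
            trial = np.where(cross, mutant, pop[i])
            f_trial = objective(trial)
            if f_trial <= fitness[i]:
                pop[i] = trial
                fitness[i] = f_trial
        best_idx = int(np.argmin(fitness))
        trace.append(fitness[best_idx])
        if len(trace) > settings.patience:
            prev = trace[-1 - settings.patience]
            if prev - trace[-1] < settings.tol * max(1.0, abs(trace[-1])):
                converged = True
                break

    return DEResult(x=pop[best_idx].copy(), fun=float(fitness[best_idx]),
                    trace=np.asarray(trace), generations=gen,
                    converged=converged, seed=settings.seed)


def _distinct_partners(rng, NP: int, i: int) -> Tuple[int, int, int]:
    idx = rng.permutation(NP)
    picked = [j for j in idx if j != i][:3]
    return picked[0], picked[1], picked[2]


# ---------------------------------------------------------------------------
# initial-condition estimation
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Estimated initial conditions plus optimisation diagnostics."""

    ic: InitialConditions
    K: float
    rss: float
    mode: str
    generations: int
    converged: bool
    trace: np.ndarray
    seed: int
    x: np.ndarray
    param_names: Tuple[str, ...]

    def to_dict(self) -> Dict[str, float]:
        d = {name: float(v) for name, v in zip(self.param_names, self.x)}
        d.update(rss=float(self.rss), generations=float(self.generations),
                 converged=float(self.converged), seed=float(self.seed))
        return d


def _vector_to_conditions(x: np.ndarray, mode: str) -> Tuple[InitialConditions, float]:
    if mode == "free_age":
        se, sn, sp_, ae, an, ap_, K = x
    else:
        se, sn, sp_, K = x
        ae = an = ap_ = 0.0
    ic = InitialConditions(egg_size=se, nymph_size=sn, pupa_size=sp_,
                           egg_age=ae, nymph_age=an, pupa_age=ap_)
    return ic, float(K)


def make_objective(monitoring: MonitoringSeries, temps: TemperatureSeries,
                   cfg: EngineConfig, mode: str = "free_age",
                   weights: Optional[Dict[str, float]] = None,
                   ) -> Callable[[np.ndarray], float]:
    """Build the DE objective: simulate from the first monitoring date
    through the last, score by pooled RSS.

    The per-day thermal responses are precomputed once (they do not depend
    on the decision vector), so each candidate evaluation only runs the
    cohort bookkeeping loop.
    """
    from .cohorts import _run_fast

    start = monitoring.first_date
    n_days = int((monitoring.last_date - start) // pd.Timedelta(days=1)) + 1
    T_seq = temps.window(start, n_days)  # fail fast if coverage is missing
    rates = precompute_rates(T_seq, cfg)

    day_idx = ((monitoring.records["date"] - start) // pd.Timedelta(days=1)
               ).to_numpy(np.int64)
    is_adult = (monitoring.records["stage"] == "adult").to_numpy(bool)
    obs = monitoring.records["count"].to_numpy(float)
    if weights is None:
        w = np.ones(len(obs))
    else:
        w = np.where(is_adult, weights.get("adult", 1.0),
                     weights.get("nymph", 1.0))

    def objective(x: np.ndarray) -> float:
        ic, K = _vector_to_conditions(x, mode)
        table = _run_fast(ic, rates, cfg.with_K(K), n_days)
        adult_total = table[day_idx, 3] + table[day_idx, 4]
        sim = np.where(is_adult, adult_total, table[day_idx, 1])
        return float(np.sum(w * (obs - sim) ** 2))

    return objective


def fit_initial_conditions(monitoring: MonitoringSeries,
                           temps: TemperatureSeries,
                           cfg: EngineConfig,
                           settings: DESettings,
                           mode: str = "free_age",
                           bounds: Optional[Dict[str, Tuple[float, float]]] = None,
                           weights: Optional[Dict[str, float]] = None,
                           init: Optional[np.ndarray] = None) -> FitResult:
    """Estimate initial cohort sizes (and, in ``free_age`` mode, initial
    physiological ages) plus K by DE over the bounded box."""
    if mode not in ("free_age", "zero_age"):
        raise ValueError(f"unknown mode {mode!r}")
    if monitoring.n_obs < 1:
        raise ValueError("monitoring series is empty")
    names = FREE_AGE_NAMES if mode == "free_age" else ZERO_AGE_NAMES
    box = dict(DEFAULT_BOUNDS)
    if bounds:
        box.update(bounds)
    bound_list = [box[n] for n in names]

    objective = make_objective(monitoring, temps, cfg, mode=mode, weights=weights)
    de = de_minimize(objective, bound_list, settings, init=init)
    ic, K = _vector_to_conditions(de.x, mode)
    return FitResult(ic=ic, K=K, rss=de.fun, mode=mode,
                     generations=de.generations, converged=de.converged,
                     trace=de.trace, seed=de.seed, x=de.x, param_names=names)
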