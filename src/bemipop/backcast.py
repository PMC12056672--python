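"""Back-casting: dating the first field infestation.

The forward model accumulates physiological age as a sum of daily
temperature-dependent development rates.  Inverting that sum dates the day a
cohort was at age zero: starting from the estimated age q at the first
monitoring date t1, step backwards one day at a time subtracting r(T_d)
(zero on days outside the permissive range) until q <= 0.  The first day on
which the running deficit reaches zero or below is the estimated origin t0
— for an egg cohort, the likely date of first oviposition, i.e. the field
invasion date.

For cohorts beyond the egg stage the inversion chains through the earlier
stages: the current stage's partial age is unwound first, then each earlier
stage's full development (age 1 -> 0), ending at egg age 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Union

import numpy as np
import pandas as pd

from .cohorts import InitialConditions
from .thermal import StageParams, development_rate
from .timeseries import TemperatureSeries

_TRACE_COLUMNS = ("date", "tmean_c", "stage", "rate", "remaining_age")

#: tie tolerance: a backward sum meant to hit exactly 0 (e.g. 0.5 - 5*0.1)
#: can overshoot/undershoot by float rounding
_TIE_EPS = 1e-9


@dataclass
class BackcastResult:
    """Estimated age-zero date with the per-day unwinding trace.

    ``residual_age`` is 0 when the temperature record sufficed to unwind the
    whole age; if the record ran out first, it holds the unexplained
    remainder and ``exhausted`` is True (t0_date is then the earliest
    temperature date, a lower bound on the true origin).
    """

    t0_date: pd.Timestamp
    days_back: int
    residual_age: float
    trace: pd.DataFrame
    exhausted: bool = False


def backcast_stage(age_at_t1: float, t1_date, temps: TemperatureSeries,
                   params: StageParams, _stage_label: Optional[str] = None,
                   ) -> BackcastResult:
    """Unwind one stage's physiological age backwards from ``t1_date``.

    ``age_at_t1`` may be 1.0 to unwind a complete stage (used when chaining
    through earlier stages).  Days are stepped from t1_date - 1 backwards;
    t0 is the first day whose subtraction drives the remaining age to zero
    or below (ties resolve to that day).
    """
    if not 0.0 <= age_at_t1 <= 1.0:
        raise ValueError("age_at_t1 must be in [0, 1]")
    t1 = pd.Timestamp(t1_date).normalize()
    label = _stage_label or params.stage_name

    q = float(age_at_t1)
    rows = []
    day = t1 - pd.Timedelta(days=1)
    days_back = 0
    exhausted = False
    t0 = t1
    while q > 0:
        if day < temps.start:
            exhausted = True
            t0 = temps.start
            break
        T = temps.at(day)
        r = development_rate(T, params)
        q -= r
        days_back += 1
        rows.append((day, T, label, r, max(q, 0.0)))
        if q <= _TIE_EPS:
            t0 = day
            q = 0.0
            break
        day -= pd.Timedelta(days=1)

    trace = pd.DataFrame(rows[::-1], columns=_TRACE_COLUMNS)
    return BackcastResult(t0_date=t0, days_back=days_back,
                          residual_age=max(q, 0.0), trace=trace,
                          exhausted=exhausted)


_STAGE_ORDER = ("egg", "nymph", "pupa")  # developmental order


def backcast_invasion(conditions: Union[InitialConditions, "FitResult"],
                      t1_date, temps: TemperatureSeries,
                      stage_params: Dict[str, StageParams]) -> BackcastResult:
    """Date the first oviposition from estimated initial conditions.

    The developmentally oldest non-empty cohort ('pupa' before nymph before
    egg) anchors the inversion; its partial age is unwound first, then each
    earlier stage's full development, ending at egg age 0 = the invasion
    date t0.
    """
    ic = getattr(conditions, "ic", conditions)
    anchor = None
    for stage in reversed(_STAGE_ORDER):
        if ic.size_of(stage) > 0:
            anchor = stage
            break
    if anchor is None:
        raise ValueError("all initial cohorts are empty; nothing to back-cast")

    t1 = pd.Timestamp(t1_date).normalize()
    chain_ages = [(anchor, ic.age_of(anchor))]
    for stage in reversed(_STAGE_ORDER[:_STAGE_ORDER.index(anchor)]):
        chain_ages.append((stage, 1.0))

    traces = []
    days_back = 0
    residual = 0.0
    current_t1 = t1
    exhausted = False
    for stage, age in chain_ages:
        res = backcast_stage(age, current_t1, temps, stage_params[stage],
                             _stage_label=stage)
        traces.append(res.trace)
        days_back += res.days_back
        current_t1 = res.t0_date
        if res.exhausted:
            residual = res.residual_age
            exhausted = True
            break

    trace = pd.concat(traces[::-1], ignore_index=True) if traces else \
        pd.DataFrame(columns=list(_TRACE_COLUMNS))
    return BackcastResult(t0_date=current_t1, days_back=days_back,
                          residual_age=residual, trace=trace,
                          exhausted=exhausted)
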