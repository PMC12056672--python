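"""Synthetic study-condition generator.

Emulates the structure of a lowland West-African cassava trial: a tropical
daily mean-temperature record (sinusoidal annual cycle plus Gaussian noise)
and stage-specific whitefly monitoring counts — adults sampled twice weekly
from about two and a half weeks after planting, nymphs weekly from about
five weeks after planting — produced by running the cohort engine forward
from a known ground truth.  Because every quantity of the generating
process is recorded in :class:`SyntheticTruth`, parameter-recovery and
round-trip tests can compare estimates against the exact truth.

The default scenario: 150 monitored days at mean 26 °C with 2 °C seasonal
amplitude and 1 °C daily noise, a single initial egg cohort of 50 at
physiological age 0.5, density dependence K = 0.01, and a 40-day
temperature pre-history for back-casting.  These are scenario defaults for
a qualitatively realistic tropical setting, not values calibrated to any
field dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .backcast import backcast_stage
from .cohorts import EngineConfig, InitialConditions, simulate
from .timeseries import MonitoringSeries, TemperatureSeries

#: day-of-week independent twice-weekly visit pattern (3/4-day alternation)
_TWICE_WEEKLY = (3, 4)


@dataclass(frozen=True)
class SamplingScheme:
    """Observation calendar relative to the first monitoring day (day 0)."""

    adult_start: int = 0        # adults observed from day 0 (= first visit)
    nymph_start: int = 18       # nymphs from ~5 weeks after planting
    adult_period: Tuple[int, ...] = _TWICE_WEEKLY
    nymph_period: Tuple[int, ...] = (7,)


@dataclass(frozen=True)
class SyntheticTruth:
    """Full generating configuration of one synthetic dataset."""

    ic: InitialConditions
    engine: EngineConfig
    t1_date: str = "1988-12-05"
    n_days: int = 150           # monitored horizon from t1
    n_days_pre: int = 40        # temperature pre-history before t1
    temp_mean: float = 26.0
    temp_amplitude: float = 2.0
    temp_noise_sd: float = 1.0
    sampling: SamplingScheme = field(default_factory=SamplingScheme)
    noise: str = "none"         # "none" | "poisson" | "negbin"
    negbin_k: float = 5.0       # negbin dispersion (smaller = noisier)
    seed: int = 0

    @property
    def K(self) -> float:
        return self.engine.crop.K


def generate_temperature(n_days: int, mean: float, seasonal_amplitude: float,
                         noise_sd: float, start_date, seed: int,
                         ) -> TemperatureSeries:
    """Sinusoidal annual cycle plus Gaussian noise, clipped to [-10, 50] °C."""
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    dates = pd.date_range(pd.Timestamp(start_date).normalize(), periods=n_days,
                          freq="D")
    doy = dates.dayofyear.to_numpy(float)
    rng = np.random.default_rng(seed)
    temps = (mean
             + seasonal_amplitude * np.sin(2 * np.pi * doy / 365.25)
             + rng.normal(0.0, noise_sd, n_days) * (noise_sd > 0))
    return TemperatureSeries(dates, np.clip(temps, -10.0, 50.0))


def truth_temperature(truth: SyntheticTruth) -> TemperatureSeries:
    """The scenario's full record: pre-history plus monitored horizon."""
    start = pd.Timestamp(truth.t1_date) - pd.Timedelta(days=truth.n_days_pre)
    return generate_temperature(truth.n_days_pre + truth.n_days,
                                truth.temp_mean, truth.temp_amplitude,
                                truth.temp_noise_sd, start, truth.seed)


def _sampling_days(start: int, period: Tuple[int, ...], horizon: int):
    day, i = start, 0
    while day < horizon:
        yield day
        day += period[i % len(period)]
        i += 1


def generate_monitoring(truth: SyntheticTruth,
                        temps: Optional[TemperatureSeries] = None,
                        ) -> MonitoringSeries:
    """Simulate the truth forward and observe it on the sampling calendar.

    With ``noise="none"`` the counts equal the simulated stage totals at the
    sampling dates exactly; Poisson noise draws counts with the simulated
    total as mean; negative-binomial noise adds overdispersion with shape
    ``negbin_k``.
    """
    if temps is None:
        temps = truth_temperature(truth)
    t1 = pd.Timestamp(truth.t1_date).normalize()
    series = simulate(truth.ic, temps, truth.engine, start_date=t1,
                      n_days=truth.n_days)
    rng = np.random.default_rng(truth.seed + 1)

    rows = []
    sch = truth.sampling
    for stage, col, start, period in (
            ("adult", "adult_total", sch.adult_start, sch.adult_period),
            ("nymph", "nymph", sch.nymph_start, sch.nymph_period)):
        for d in _sampling_days(start, period, truth.n_days):
            mu = float(series.column(col)[d])
            rows.append((t1 + pd.Timedelta(days=d), stage,
                         _observe(mu, truth.noise, truth.negbin_k, rng)))
    return MonitoringSeries(pd.DataFrame(rows, columns=["date", "stage", "count"]))


def _observe(mu: float, noise: str, negbin_k: float, rng) -> float:
    if noise == "none":
        return mu
    if noise == "poisson":
        return float(rng.poisson(mu))
    if noise == "negbin":
        if mu <= 0:
            return 0.0
        p = negbin_k / (negbin_k + mu)
        return float(rng.negative_binomial(negbin_k, p))
    raise ValueError(f"unknown noise model {noise!r}")


def true_oviposition_date(truth: SyntheticTruth,
                          temps: Optional[TemperatureSeries] = None,
                          ) -> pd.Timestamp:
    """The scenario's first-oviposition date.

    The generator fixes the initial egg age as a primitive, so its origin
    date is defined by inverting the forward ageing process under the TRUE
    egg parameters and TRUE temperatures.
    """
    if temps is None:
        temps = truth_temperature(truth)
    res = backcast_stage(truth.ic.egg_age, truth.t1_date, temps,
                         truth.engine.stage_params["egg"])
    return res.t0_date


def default_scenario(seed: int = 0, noise: str = "none",
                     ic: Optional[InitialConditions] = None,
                     engine: Optional[EngineConfig] = None) -> SyntheticTruth:
    """The package's reference synthetic scenario (see module docstring)."""
    if ic is None:
        ic = InitialConditions(egg_size=50.0, egg_age=0.5)
    if engine is None:
        engine = EngineConfig().with_K(0.01)
    return SyntheticTruth(ic=ic, engine=engine, noise=noise, seed=seed)


def generate_dataset(truth: SyntheticTruth):
    """Convenience: (temps, monitoring, true t0) for one truth."""
    temps = truth_temperature(truth)
    monitoring = generate_monitoring(truth, temps)
    t0 = true_oviposition_date(truth, temps)
    return temps, monitoring, t0
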