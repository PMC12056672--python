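"""Shared fixtures: constant-rate engine configs for hand-arithmetic
oracles, and the default synthetic scenario with its (expensive) DE fits
computed once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from bemipop import (AdultParams, CropParams, DESettings, EngineConfig,
                     LethalLimits, StageParams, TemperatureSeries,
                     default_scenario, fit_initial_conditions,
                     generate_dataset, register_rate_form)


def _const(x, c):
    return np.full_like(np.asarray(x, dtype=float), c)


register_rate_form("const", _const)


def const_engine(r_egg=0.25, r_nymph=0.25, r_pupa=0.25, m=0.0,
                 phi=0.0, psi=0.0, sen=0.0, K=0.0,
                 TL=0.0, TU=50.0, lethal=LethalLimits(4.0, 36.0),
                 **kwargs) -> EngineConfig:
    """Engine with temperature-independent rates so stage durations and egg
    outputs follow exact hand arithmetic."""
    stage_params = {
        name: StageParams(name, TL=TL, TU=TU, dev_form="const",
                          dev_params=(r,), mort_form="const", mort_params=(m,))
        for name, r in (("egg", r_egg), ("nymph", r_nymph), ("pupa", r_pupa))
    }
    adult = AdultParams(sex_ratio=0.5, repro_T_range=(4.0, 36.0),
                        ovi_form="const", ovi_params=(phi,),
                        cap_form="const", cap_params=(psi,),
                        sen_form="const", sen_params=(sen,))
    crop = CropParams(K=K, cs_form="const", cs_params=(1.0,))
    return EngineConfig(stage_params=stage_params, adult_params=adult,
                        lethal=lethal, crop=crop, planting_offset=0, **kwargs)


def constant_temps(n_days: int, T: float = 26.0,
                   start: str = "1988-12-05") -> TemperatureSeries:
    return TemperatureSeries(pd.date_range(start, periods=n_days, freq="D"),
                             np.full(n_days, float(T)))


@pytest.fixture(scope="session")
def scenario():
    """Default noiseless synthetic scenario: truth, temps, monitoring,
    true first-oviposition date."""
    truth = default_scenario(seed=1)
    temps, monitoring, true_t0 = generate_dataset(truth)
    return truth, temps, monitoring, true_t0


#: one DE budget shared by both estimation arms
FIT_SETTINGS = DESettings(seed=7, max_generations=400)


@pytest.fixture(scope="session")
def free_fit(scenario):
    truth, temps, monitoring, _ = scenario
    return fit_initial_conditions(monitoring, temps, truth.engine,
                                  FIT_SETTINGS, mode="free_age")


@pytest.fixture(scope="session")
def zero_fit(scenario):
    truth, temps, monitoring, _ = scenario
    return fit_initial_conditions(monitoring, temps, truth.engine,
                                  FIT_SETTINGS, mode="zero_age")
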