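"""Cohort engine: hand-arithmetic stage timings, conservation, determinism."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bemipop import (EngineConfig, InitialConditions, init_state, simulate,
                     step_day)
from conftest import const_engine, constant_temps


class TestInitState:
    def test_all_zero_sizes_gives_empty_state(self):
        state = init_state(InitialConditions(), "1988-12-05")
        assert state.n_cohorts == 0 and state.day == 0

    def test_single_egg_cohort(self):
        state = init_state(InitialConditions(egg_size=10.0), "1988-12-05")
        cohorts = state.cohorts()
        assert len(cohorts) == 1
        assert cohorts[0].stage == "egg"
        assert cohorts[0].size == 10.0 and cohorts[0].age == 0.0

    def test_age_bound_is_legal(self):
        ic = InitialConditions(pupa_size=1.0, pupa_age=0.99)
        assert init_state(ic, "1988-12-05").cohorts()[0].age == 0.99

    @pytest.mark.parametrize("kwargs", [
        dict(egg_size=-1.0), dict(egg_size=2e6),
        dict(nymph_size=1.0, nymph_age=1.0), dict(pupa_age=-0.1, pupa_size=1.0),
    ])
    def test_out_of_bound_conditions_rejected(self, kwargs):
        with pytest.raises(ValueError):
            InitialConditions(**kwargs)


class TestStepDay:
    def test_empty_state_steps_forward(self):
        cfg = const_engine()
        state = init_state(InitialConditions(), "1988-12-05")
        new = step_day(state, 26.0, cfg)
        assert new.n_cohorts == 0 and new.day == 1
        assert state.day == 0  # functional update

    def test_nonfinite_temperature_rejected(self):
        cfg = const_engine()
        state = init_state(InitialConditions(egg_size=1.0), "1988-12-05")
        with pytest.raises(ValueError, match="non-finite"):
            step_day(state, float("nan"), cfg)

    def test_lethal_temperature_removes_immatures(self):
        cfg = const_engine()
        state = init_state(InitialConditions(egg_size=10, nymph_size=5,
                                             pupa_size=2), "1988-12-05")
        new = step_day(state, 40.0, cfg)  # beyond ULT = 36
        assert new.n_cohorts == 0

    @pytest.mark.parametrize("r0,r,expected_days", [
        (0.0, 0.25, 4),    # 4 x 0.25 = 1
        (0.5, 0.1, 5),     # ceil(0.5/0.1)
        (0.62, 0.1, 4),    # ceil(0.38/0.1)
        (0.0, 0.3, 4),     # ceil(1/0.3), overshoot discarded
    ])
    def test_transition_day_matches_hand_count(self, r0, r, expected_days):
        """Stage completion at constant T follows ceil((1-r0)/r(T))."""
        cfg = const_engine(r_egg=r)
        temps = constant_temps(expected_days + 3)
        ic = InitialConditions(egg_size=10.0, egg_age=r0)
        series = simulate(ic, temps, cfg)
        nymph = series.column("nymph")
        first = int(np.argmax(nymph > 0))
        assert first == expected_days
        assert math.ceil((1.0 - r0) / r) == expected_days

    def test_reproduction_hand_example(self):
        """100 adults, SR=0.5, phi=0.1, psi=2 lay a 10-egg cohort on day 1."""
        cfg = const_engine(phi=0.1, psi=2.0)
        temps = constant_temps(3)
        ic = InitialConditions(adult_size=100.0)
        series = simulate(ic, temps, cfg)
        assert series.column("egg")[0] == 0.0
        assert series.column("egg")[1] == pytest.approx(10.0)

    def test_fecund_period_and_senescence_timing(self):
        """phi=0.1 completes the fecund period on its 10th accumulation;
        senescence 0.2 then removes the cohort after 5 accumulations (the
        first lands on the day the cohort turns post-reproductive)."""
        cfg = const_engine(phi=0.1, psi=0.0, sen=0.2)
        temps = constant_temps(20)
        series = simulate(InitialConditions(adult_size=50.0), temps, cfg)
        repro = series.column("adult_repro")
        post = series.column("adult_post")
        assert np.all(repro[:10] == 50.0) and np.all(post[:10] == 0.0)
        assert repro[10] == 0.0 and np.all(post[10:14] == 50.0)
        assert post[14] == 0.0


class TestSimulate:
    def test_zero_population_stays_zero(self):
        series = simulate(InitialConditions(), constant_temps(30), const_engine())
        assert np.all(series.table == 0.0)

    def test_conservation_through_all_transitions(self):
        """No mortality, no reproduction: total population is conserved
        through egg -> nymph -> pupa -> adult."""
        cfg = const_engine(r_egg=0.2, r_nymph=0.25, r_pupa=0.5)
        temps = constant_temps(20)
        series = simulate(InitialConditions(egg_size=37.0), temps, cfg)
        totals = series.table.sum(axis=1)
        assert np.allclose(totals, 37.0)
        assert series.column("adult_repro")[5 + 4 + 2] == pytest.approx(37.0)

    def test_total_nonincreasing_without_reproduction(self):
        cfg = const_engine(m=0.1, K=0.01)
        temps = constant_temps(40)
        ic = InitialConditions(egg_size=100, nymph_size=50, pupa_size=25)
        series = simulate(ic, temps, cfg)
        totals = series.table.sum(axis=1)
        assert np.all(np.diff(totals) <= 1e-12)

    def test_ageing_frozen_outside_permissive_range(self):
        """Days below TL neither advance age nor (being above LLT) kill."""
        cfg = const_engine(r_egg=0.25, TL=10.0, TU=35.0)
        dates = pd.date_range("1988-12-05", periods=8, freq="D")
        # two cold (but non-lethal) days delay the 4-day transition to day 6
        tmean = np.array([26, 8.0, 8.0, 26, 26, 26, 26, 26], dtype=float)
        from bemipop import TemperatureSeries
        temps = TemperatureSeries(dates, tmean)
        series = simulate(InitialConditions(egg_size=10.0), temps, cfg)
        assert np.argmax(series.column("nymph") > 0) == 6

    def test_missing_temperature_coverage_names_date(self):
        temps = constant_temps(5)
        with pytest.raises(KeyError, match="1988-12-1"):
            simulate(InitialConditions(egg_size=1.0), temps, const_engine(),
                     n_days=10)

    def test_determinism_bit_identical(self, scenario):
        truth, temps, _, _ = scenario
        a = simulate(truth.ic, temps, truth.engine, start_date=truth.t1_date,
                     n_days=80)
        b = simulate(truth.ic, temps, truth.engine, start_date=truth.t1_date,
                     n_days=80)
        assert np.array_equal(a.table, b.table)

    def test_fast_path_matches_step_day_reference(self, scenario):
        """The vectorised daily loop reproduces repeated step_day exactly."""
        truth, temps, _, _ = scenario
        n = 80
        series = simulate(truth.ic, temps, truth.engine,
                          start_date=truth.t1_date, n_days=n)
        state = init_state(truth.ic, truth.t1_date)
        T = temps.window(series.dates[0], n)
        for d in range(n):
            assert np.array_equal(state.totals(), series.table[d])
            state = step_day(state, float(T[d]), truth.engine)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(r0=st.floats(0.0, 0.99), r=st.floats(0.02, 0.9))
def test_completion_day_property(r0, r):
    """ceil((1-r0)/r) forward-counted days completes the stage at any
    constant permissive temperature."""
    expected = math.ceil((1.0 - r0) / r)
    cfg = const_engine(r_egg=r)
    temps = constant_temps(expected + 2)
    series = simulate(InitialConditions(egg_size=1.0, egg_age=r0), temps, cfg)
    assert int(np.argmax(series.column("nymph") > 0)) == expected


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_age_monotone_under_random_temperatures(seed):
    """Cohort physiological age never decreases, whatever the weather."""
    from bemipop import generate_temperature
    temps = generate_temperature(40, 22.0, 8.0, 6.0, "1988-12-05", seed)
    cfg = EngineConfig()
    state = init_state(InitialConditions(egg_size=5.0, egg_age=0.1),
                       "1988-12-05")
    last_age = 0.0
    for d in range(40):
        if state.n_cohorts == 0 or state.cohorts()[0].stage != "egg":
            break
        age = state.cohorts()[0].age
        assert age >= last_age - 1e-15
        last_age = age
        state = step_day(state, temps.tmean[d], cfg)
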