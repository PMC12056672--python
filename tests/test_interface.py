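"""File dialects round-trip through their readers; the CLI orchestrates the
workflow and fails cleanly on bad input."""

import numpy as np
import pandas as pd
import pytest
import yaml

from bemipop import (InitialConditions, default_scenario, generate_dataset,
                     load_config, read_monitoring, read_stage_series,
                     read_temperature, simulate, write_monitoring,
                     write_stage_series, write_temperature)
from bemipop.cli import main
from bemipop.config import (default_config_dict, dump_default_config,
                            engine_config_from_dict)
from conftest import const_engine, constant_temps


@pytest.fixture(scope="module")
def fixtures_dir(tmp_path_factory):
    """Synthetic temperature/monitoring CSVs written once for CLI tests."""
    d = tmp_path_factory.mktemp("fixtures")
    truth = default_scenario(seed=6)
    temps, monitoring, _ = generate_dataset(truth)
    write_temperature(temps, d / "temperature.csv")
    write_monitoring(monitoring, d / "monitoring.csv")
    return d, truth, temps, monitoring


class TestReaders:
    def test_temperature_roundtrip(self, tmp_path, fixtures_dir):
        d, _, temps, _ = fixtures_dir
        back = read_temperature(d / "temperature.csv")
        assert np.array_equal(back.tmean, temps.tmean)
        assert back.dates.equals(temps.dates)

    def test_temperature_gap_named(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("date,tmean_c\n1988-12-05,26\n1988-12-07,25\n")
        with pytest.raises(ValueError, match="1988-12-06"):
            read_temperature(p)

    def test_non_numeric_temperature_row_named(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("date,tmean_c\n1988-12-05,26\n1988-12-06,abc\n")
        with pytest.raises(ValueError, match="row\\(s\\) \\[3\\]"):
            read_temperature(p)

    def test_monitoring_roundtrip(self, fixtures_dir):
        d, _, _, monitoring = fixtures_dir
        back = read_monitoring(d / "monitoring.csv")
        assert back.records.equals(monitoring.records)

    def test_unknown_stage_rejected(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("date,stage,count\n1988-12-05,larva,3\n")
        with pytest.raises(ValueError, match="larva"):
            read_monitoring(p)

    def test_negative_count_rejected(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("date,stage,count\n1988-12-05,adult,-3\n")
        with pytest.raises(ValueError, match="non-negative"):
            read_monitoring(p)

    def test_stage_series_roundtrip(self, tmp_path):
        series = simulate(InitialConditions(egg_size=10.0, adult_size=4.0),
                          constant_temps(15), const_engine(phi=0.1, psi=20.0))
        write_stage_series(series, tmp_path / "s.csv")
        back = read_stage_series(tmp_path / "s.csv")
        assert np.array_equal(back.table, series.table)


class TestConfig:
    def test_default_config_roundtrip(self, tmp_path):
        p = tmp_path / "config.yaml"
        dump_default_config(p)
        cfg = load_config(p)
        assert cfg == default_config_dict()
        engine_config_from_dict(cfg)  # builds without error

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="unknown config key"):
            engine_config_from_dict({"tyypo": 1})


class TestCli:
    def test_simulate_zero_population(self, tmp_path, fixtures_dir):
        d, *_ = fixtures_dir
        rc = main(["simulate", "--temperature", str(d / "temperature.csv"),
                   "--outdir", str(tmp_path)])
        assert rc == 0
        out = pd.read_csv(tmp_path / "stage_series.csv")
        assert (out[["egg", "nymph", "pupa", "adult_total"]] == 0).all().all()

    def test_missing_input_file_diagnosed(self, tmp_path, capsys):
        rc = main(["simulate", "--temperature", str(tmp_path / "nope.csv")])
        assert rc != 0
        assert "nope.csv" in capsys.readouterr().err

    def test_backcast_explicit_age(self, tmp_path, fixtures_dir, capsys):
        d, truth, *_ = fixtures_dir
        rc = main(["backcast", "--temperature", str(d / "temperature.csv"),
                   "--t1", str(pd.Timestamp(truth.t1_date).date()),
                   "--r0", "0.5", "--outdir", str(tmp_path)])
        assert rc == 0
        printed = capsys.readouterr().out.strip().splitlines()[-1]
        assert pd.Timestamp(printed) < pd.Timestamp(truth.t1_date)
        trace = pd.read_csv(tmp_path / "backcast_trace.csv")
        assert set(trace.columns) >= {"date", "tmean_c", "rate",
                                      "remaining_age"}

    def test_fit_then_backcast_workflow(self, tmp_path, fixtures_dir, capsys):
        """A tiny-budget fit runs end to end and back-casts from its
        estimates (accuracy is covered by the acceptance suite)."""
        d, truth, *_ = fixtures_dir
        cfgp = tmp_path / "config.yaml"
        cfg = default_config_dict()
        cfg["de"].update(pop_size=8, max_generations=3)
        cfg["crop"]["K"] = truth.K
        cfgp.write_text(yaml.safe_dump(cfg))
        rc = main(["fit", "--temperature", str(d / "temperature.csv"),
                   "--monitoring", str(d / "monitoring.csv"),
                   "--config", str(cfgp), "--seed", "3",
                   "--outdir", str(tmp_path)])
        assert rc == 0
        assert (tmp_path / "fit_result.kv").exists()
        trace = pd.read_csv(tmp_path / "de_trace.csv")
        assert np.all(np.diff(trace["best_rss"]) <= 0)
        rc = main(["backcast", "--temperature", str(d / "temperature.csv"),
                   "--t1", str(pd.Timestamp(truth.t1_date).date()),
                   "--fit-result", str(tmp_path / "fit_result.kv"),
                   "--outdir", str(tmp_path)])
        assert rc == 0

    def test_evaluate_subcommand(self, tmp_path, fixtures_dir, capsys):
        d, truth, temps, monitoring = fixtures_dir
        series = simulate(truth.ic, temps, truth.engine,
                          start_date=truth.t1_date, n_days=truth.n_days)
        write_stage_series(series, tmp_path / "sim.csv")
        rc = main(["evaluate", "--monitoring", str(d / "monitoring.csv"),
                   "--simulated", str(tmp_path / "sim.csv"),
                   "--stage", "nymph", "--outdir", str(tmp_path)])
        assert rc == 0
        out = capsys.readouterr().out
        assert "R^2" in out and (tmp_path / "evaluation.kv").exists()

    def test_synth_subcommand_writes_fixtures(self, tmp_path):
        rc = main(["synth", "--seed", "4", "--outdir", str(tmp_path)])
        assert rc == 0
        for name in ("temperature.csv", "monitoring.csv", "truth.json"):
            assert (tmp_path / name).exists()
        read_temperature(tmp_path / "temperature.csv")
        read_monitoring(tmp_path / "monitoring.csv")
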