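"""Replicate statistics, derived metrics and the CLI surface."""

import math

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from isletsim import (CIResult, ModelParams, ScenarioConfig, cancer_fraction_series,
                      confidence_interval, initialize, run)
from isletsim.cli import main
from isletsim.reporting import summarize_run


class TestConfidenceInterval:
    def test_constant_sample_collapses(self):
        ci = confidence_interval([0.5, 0.5, 0.5])
        assert ci.lower == ci.mean == ci.upper == 0.5

    def test_printed_formula_example(self):
        """n=10, mean 0.5, sigma 0.1 -> (0.438, 0.562)."""
        x = np.array([0.35, 0.40, 0.45, 0.45, 0.50, 0.50, 0.55, 0.55, 0.60, 0.65])
        x = 0.5 + (x - x.mean()) * (0.1 / x.std(ddof=1))
        ci = confidence_interval(x)
        assert ci.mean == pytest.approx(0.5, abs=1e-12)
        assert ci.lower == pytest.approx(0.5 - 1.96 * 0.1 / math.sqrt(10), abs=1e-9)
        assert ci.upper == pytest.approx(0.5 + 1.96 * 0.1 / math.sqrt(10), abs=1e-9)

    def test_brute_force_oracle(self, rng):
        """Agrees with a direct reimplementation of the z-interval to 1e-12."""
        for _ in range(20):
            x = rng.normal(size=rng.integers(2, 40))
            ci = confidence_interval(x)
            mean = sum(x) / len(x)
            sigma = math.sqrt(sum((v - mean) ** 2 for v in x) / (len(x) - 1))
            half = 1.96 * sigma / math.sqrt(len(x))
            assert ci.mean == pytest.approx(mean, abs=1e-12)
            assert ci.lower == pytest.approx(mean - half, abs=1e-12)
            assert ci.upper == pytest.approx(mean + half, abs=1e-12)

    def test_single_sample_degenerate_with_warning(self):
        with pytest.warns(UserWarning):
            ci = confidence_interval([0.7])
        assert ci == CIResult(0.7, 0.7, 0.7, 1)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            confidence_interval([])


def _summary(series_rows, scenario=None, seed=0):
    sc = scenario or ScenarioConfig(t_end=series_rows[-1][0], seed=seed)
    frame = pd.DataFrame(series_rows, columns=["time_min", "n_epithelial",
                                               "n_cancer", "n_tcell",
                                               "cancer_fraction"])
    return summarize_run(frame, seed=seed, scenario=sc)


class TestRunSummary:
    def test_response_time_first_return_to_zero(self):
        s = _summary([(0, 10, 0, 0, 0.0), (10, 10, 1, 5, 0.0625),
                      (20, 10, 2, 5, 0.117), (30, 10, 0, 5, 0.0),
                      (40, 10, 1, 5, 0.0625), (50, 10, 0, 5, 0.0)])
        assert s.immune_response_time == 30.0
        assert not s.censored
        assert s.max_cancer_fraction == pytest.approx(0.117)

    def test_censored_when_never_cleared(self):
        s = _summary([(0, 10, 0, 0, 0.0), (10, 9, 1, 5, 0.0667),
                      (20, 8, 3, 5, 0.1875)])
        assert s.censored
        assert s.immune_response_time == 20.0  # reported at t_end, flagged

    def test_no_tumor_is_censored_with_zero_fraction(self):
        s = _summary([(0, 10, 0, 0, 0.0), (10, 12, 0, 0, 0.0)])
        assert s.censored
        assert s.max_cancer_fraction == 0.0


class TestFractionSeries:
    def test_single_replicate_zero_width_band(self):
        s = _summary([(0, 10, 0, 0, 0.0), (10, 10, 2, 0, 1 / 6)])
        band = cancer_fraction_series([s])
        assert np.allclose(band["mean"], band["lower"])
        assert np.allclose(band["mean"], band["upper"])

    def test_identical_replicates_zero_width_band(self):
        rows = [(0, 10, 0, 0, 0.0), (10, 10, 2, 0, 1 / 6), (20, 10, 4, 0, 0.4)]
        band = cancer_fraction_series([_summary(rows), _summary(rows)])
        assert np.allclose(band["upper"] - band["lower"], 0.0)

    def test_band_width_scales_with_replicates(self, rng):
        """Half-width tracks 1.96 sigma / sqrt(n) at each time point."""
        def noisy(seed):
            r = np.random.default_rng(seed)
            f = float(r.uniform(0.1, 0.3))
            return _summary([(0, 10, 0, 0, 0.0), (10, 10, 2, 0, f)], seed=0)
        replicates = [noisy(i) for i in range(10)]
        band = cancer_fraction_series(replicates)
        fractions = [s.series["cancer_fraction"].iloc[-1] for s in replicates]
        half = 1.96 * np.std(fractions, ddof=1) / math.sqrt(10)
        row = band.iloc[-1]
        assert row["upper"] - row["mean"] == pytest.approx(half, rel=1e-9)

    def test_mixed_scenarios_rejected(self):
        a = _summary([(0, 10, 0, 0, 0.0)], ScenarioConfig(t_end=0.0, k=0.0))
        b = _summary([(0, 10, 0, 0, 0.0)], ScenarioConfig(t_end=0.0, k=0.3))
        with pytest.raises(ValueError):
            cancer_fraction_series([a, b])

    def test_step_interpolation_onto_common_grid(self):
        a = _summary([(0, 10, 0, 0, 0.0), (10, 10, 0, 0, 0.2)])
        b = _summary([(0, 10, 0, 0, 0.1), (5, 10, 0, 0, 0.3), (10, 10, 0, 0, 0.3)])
        band = cancer_fraction_series([a, b])
        at5 = band.loc[band["time_min"] == 5.0].iloc[0]
        assert at5["mean"] == pytest.approx((0.0 + 0.3) / 2)


class TestTimeseriesRoundTrip:
    def test_written_series_parses_back_exactly(self, tmp_path):
        params = ModelParams()
        sc = ScenarioConfig(islet_radius=6.0, t_end=3.0, immunity="none", seed=5,
                            snapshot_times=())
        state = initialize(sc, params, rng=np.random.default_rng(5))
        summary = run(state, outdir=tmp_path)
        read_back = pd.read_csv(tmp_path / "timeseries.csv")
        pd.testing.assert_frame_equal(read_back, summary.series, check_exact=False,
                                      rtol=1e-14)


class TestCli:
    def test_calibrate_reports_derived_constants(self):
        result = CliRunner().invoke(main, ["calibrate"])
        assert result.exit_code == 0
        assert '"M0"' in result.output
        assert '"equilibrium_overlap_um"' in result.output

    def test_energy_curves_reports_equilibrium(self):
        result = CliRunner().invoke(main, ["energy-curves"])
        assert result.exit_code == 0
        assert "equilibrium overlap" in result.output

    def test_run_twice_identical_timeseries(self, tmp_path):
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text("islet_radius: 6\nt_end: 3\nimmunity: none\n"
                       "snapshot_times: []\n")
        args = ["run", "--config", str(cfg), "--seed", "4"]
        r1 = CliRunner().invoke(main, args + ["--out", str(tmp_path / "a")])
        r2 = CliRunner().invoke(main, args + ["--out", str(tmp_path / "b")])
        assert r1.exit_code == 0, r1.output
        assert r2.exit_code == 0
        assert (tmp_path / "a" / "timeseries.csv").read_bytes() == \
               (tmp_path / "b" / "timeseries.csv").read_bytes()

    def test_bad_flag_is_usage_error(self):
        result = CliRunner().invoke(main, ["run", "--no-such-flag"])
        assert result.exit_code != 0
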