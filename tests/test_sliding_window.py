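import numpy as np
import pytest

import phenocue as pc
from phenocue import regression_core as rc
from phenocue import sliding_window as sw


class TestAggregate:
    def test_basic_statistics(self):
        temps = [10.0, 12.0, 14.0]
        assert sw.aggregate(temps, "mean") == 12.0
        assert sw.aggregate(temps, "min") == 10.0
        assert sw.aggregate(temps, "max") == 14.0

    def test_slope_exact_on_collinear(self):
        # oldest -> newest warming by 2 °C/day
        assert sw.aggregate([10.0, 12.0, 14.0], "slope") == pytest.approx(2.0)

    def test_slope_constant_series(self):
        assert sw.aggregate([5.0, 5.0, 5.0, 5.0], "slope") == pytest.approx(0.0)

    def test_slope_one_day_rejected(self):
        with pytest.raises(ValueError, match="1-day"):
            sw.aggregate([5.0], "slope")

    def test_one_day_window_mean_min_max_agree(self):
        for v in (3.2, -1.0):
            assert (
                sw.aggregate([v], "mean")
                == sw.aggregate([v], "min")
                == sw.aggregate([v], "max")
            )


def brute_force_search(phenology, matrix, statistics, max_duration):
    """Independent double-loop oracle over all candidate windows."""
    y = phenology.event_day.astype(float)
    baseline = rc.aicc_intercept_only(y)
    rows = []
    lags = matrix.lags
    for ci in range(len(lags)):
        for oi in range(ci, min(ci + max_duration, len(lags))):
            for stat in statistics:
                if stat == "slope" and oi == ci:
                    continue
                x = np.array(
                    [
                        sw.aggregate(matrix.values[i, ci : oi + 1][::-1], stat)
                        for i in range(len(y))
                    ]
                )
                fit = rc.fit_linear(x, y)
                rows.append(
                    {
                        "statistic": stat,
                        "open": int(lags[oi]),
                        "close": int(lags[ci]),
                        "aicc": rc.aicc(fit),
                        "slope": fit.slope,
                        "r2_adj": fit.r2_adj,
                    }
                )
    return baseline, rows


class TestSearchAbsolute:
    def test_matches_bruteforce_oracle(self, toy_phenology, toy_matrix):
        """Ranked list identical to the double-loop oracle on a 10-lag toy."""
        stats = ("mean", "min", "max", "slope")
        result = sw.search_absolute(toy_phenology, toy_matrix, stats, 10)
        baseline, rows = brute_force_search(toy_phenology, toy_matrix, stats, 10)
        assert result.baseline_aicc == pytest.approx(baseline, abs=1e-10)
        oracle = {
            (r["statistic"], r["open"], r["close"]): r for r in rows
        }
        assert len(result.table) == len(oracle)
        for _, row in result.table.iterrows():
            key = (row["statistic"], int(row["open"]), int(row["close"]))
            assert abs(row["aicc"] - oracle[key]["aicc"]) < 1e-8
            assert row["slope"] == pytest.approx(oracle[key]["slope"], abs=1e-9)
        # ranking agrees with sorting the oracle by AICc
        best_oracle = min(rows, key=lambda r: r["aicc"])
        best = result.best
        assert best.aicc == pytest.approx(best_oracle["aicc"], abs=1e-8)

    def test_candidate_count(self, toy_phenology, toy_matrix):
        """|stats| * D(D+1)/2 minus the 1-day slope windows."""
        L = len(toy_matrix.lags)
        result = sw.search_absolute(
            toy_phenology, toy_matrix, ("mean", "min", "max", "slope"), L
        )
        n_windows = L * (L + 1) // 2
        assert len(result.table) == 4 * n_windows - L

    def test_zero_noise_planted_window(self):
        climate = pc.simulate_climate(pc.ClimateGenSpec(seed=40))
        spec = pc.PhenoGenSpec(
            window=sw.WindowSpec(60, 30, "absolute", "mean"),
            intercept=74.0, slope=-6.0, noise_sd=0.0, seed=41,
        )
        pheno, _ = pc.simulate_phenology(
            climate, spec, years=np.arange(1961, 2011)
        )
        matrix = pc.build_climate_matrix(climate, pheno.years)
        best = sw.search_absolute(pheno, matrix, ("mean",), 365).best
        # whole-day rounding of the generated means is the only noise;
        # at these scales it caps attainable R² just below 0.999
        assert best.fit.r2 > 0.99
        assert best.window.close <= 60 and best.window.open >= 30  # overlaps truth

    def test_years_mismatch_subsets_matrix(self, scenario, scenario_matrix):
        _, pheno, _ = scenario
        sub = pheno.subset(1971, 2000)
        res = sw.search_absolute(sub, scenario_matrix, ("mean",), 30)
        assert res.n_years == 30


class TestSearchRelative:
    def test_self_consistent_construction_recovered(self):
        """Zero-noise event-anchored cue: a ~30-day-before-event window
        attains near-perfect fit (whole-day rounding is the only noise)."""
        climate = pc.simulate_climate(pc.ClimateGenSpec(seed=42))
        spec = pc.PhenoGenSpec(
            window=sw.WindowSpec(30, 1, "relative", "mean"),
            intercept=74.0, slope=-6.0, noise_sd=0.0, seed=43,
        )
        pheno, _ = pc.simulate_phenology(climate, spec, years=np.arange(1961, 2011))
        res = sw.search_relative(pheno, climate, ("mean",), 365)
        best = res.best
        # whole-day self-consistency leaves ~1 day of discretization noise
        assert best.fit.r2 > 0.9
        assert best.window.close <= 30 and best.window.open >= 1
        assert best.fit.slope == pytest.approx(-6.0, abs=0.3)

    def test_single_year_rejected(self):
        climate = pc.simulate_climate(pc.ClimateGenSpec(seed=1, end_year=1963))
        pheno = pc.PhenologySeries([1962], [30])
        with pytest.raises(pc.ValidationError, match="4 years"):
            sw.search_relative(pheno, climate)


class TestPredictFromCue:
    def test_arithmetic(self):
        fit = rc.fit_linear(
            np.array([8.0, 9.0, 10.0, 11.0, 12.0]),
            160 - 6 * np.array([8.0, 9.0, 10.0, 11.0, 12.0]),
        )
        model = sw.CueModel(sw.WindowSpec(5, 3, "absolute", "mean"), fit, (2000, 2004))
        matrix = pc.ClimateMatrix(
            [2010], np.arange(10), np.full((1, 10), 10.0)
        )
        preds = sw.predict_from_cue(model, matrix)
        assert preds[0].predicted == pytest.approx(100.0)

    def test_training_year_equals_fitted_value(self, scenario, scenario_matrix):
        _, pheno, _ = scenario
        res = sw.search_absolute(pheno, scenario_matrix, ("mean",), 120)
        model = res.best_model()
        preds = sw.predict_from_cue(model, scenario_matrix.select_years([1980]))
        x = sw.window_aggregate_series(
            scenario_matrix.select_years([1980]), model.window
        )[0]
        assert preds[0].predicted == pytest.approx(
            model.fit.intercept + model.fit.slope * x
        )

    def test_relative_frame_refused(self):
        fit = rc.fit_linear(np.arange(5.0), 2 * np.arange(5.0) + 1e-9 * np.arange(5.0) ** 2)
        model = sw.CueModel(sw.WindowSpec(30, 1, "relative", "mean"), fit, (2000, 2004))
        matrix = pc.ClimateMatrix([2010], np.arange(40), np.zeros((1, 40)))
        with pytest.raises(pc.ValidationError, match="already occurred"):
            sw.predict_from_cue(model, matrix)


class TestWindowSpec:
    def test_invalid_windows_rejected(self):
        with pytest.raises(ValueError):
            sw.WindowSpec(3, 5)
        with pytest.raises(ValueError):
            sw.WindowSpec(5, -1)
        with pytest.raises(ValueError):
            sw.WindowSpec(5, 1, "absolute", "median")

    def test_duration(self):
        assert sw.WindowSpec(81, 14).duration == 68
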