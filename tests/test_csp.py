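import subprocess
import textwrap

import numpy as np
import pytest

import phenocue as pc
from phenocue import csp
from phenocue import sliding_window as sw


class TestDailyRegressions:
    def test_output_length_matches_lags(self, scenario):
        climate, pheno, _ = scenario
        m = pc.build_climate_matrix(climate, pheno.years, include_reference_day=False)
        coef, r2 = csp.daily_regressions(pheno, m)
        assert len(coef) == len(r2) == 365
        m0 = pc.build_climate_matrix(climate, pheno.years, n_lags=364)
        coef0, _ = csp.daily_regressions(pheno, m0)
        assert len(coef0) == 364

    def test_identical_columns_identical_results(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(12, 5))
        values[:, 3] = values[:, 1]
        m = pc.ClimateMatrix(np.arange(2000, 2012), np.arange(5), values)
        pheno = pc.PhenologySeries(m.years, rng.integers(20, 40, 12))
        coef, r2 = csp.daily_regressions(pheno, m)
        assert coef[3] == coef[1] and r2[3] == r2[1]

    def test_degenerate_lag_warns_and_zeroes(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(10, 4))
        values[:, 2] = 7.0
        m = pc.ClimateMatrix(np.arange(2000, 2010), np.arange(4), values)
        pheno = pc.PhenologySeries(m.years, rng.integers(20, 40, 10))
        with pytest.warns(UserWarning, match="constant temperature"):
            coef, r2 = csp.daily_regressions(pheno, m)
        assert coef[2] == 0.0 and r2[2] == 0.0

    def test_null_system_low_r2(self):
        """Phenology independent of climate: mean per-lag R² stays small."""
        climate = pc.simulate_climate(pc.ClimateGenSpec(seed=50))
        rng = np.random.default_rng(51)
        years = np.arange(1961, 2011)  # n = 50
        pheno = pc.PhenologySeries(years, rng.integers(20, 40, len(years)))
        m = pc.build_climate_matrix(climate, years, include_reference_day=False)
        _, r2 = csp.daily_regressions(pheno, m)
        assert r2.mean() < 0.15


class TestSmoothProfile:
    def test_constant_input_constant_output(self):
        out = csp.smooth_profile(np.full(100, 3.7))
        assert np.allclose(out, 3.7, atol=1e-6)

    def test_beats_straight_line_on_curved_input(self):
        x = np.arange(120.0)
        y = np.sin(x / 15.0)
        smooth = csp.smooth_profile(y, x, basis_dim=30)
        rss_smooth = ((y - smooth) ** 2).sum()
        coefs = np.polyfit(x, y, 1)
        rss_line = ((y - np.polyval(coefs, x)) ** 2).sum()
        assert rss_smooth <= rss_line

    def test_noisy_sine_recovery(self):
        """Smoothing gets closer to the true curve than the raw values."""
        rng = np.random.default_rng(5)
        lags = np.arange(1, 366)
        truth = np.sin(2 * np.pi * lags / 365.0)
        noisy = truth + rng.normal(0, 0.5, len(lags))
        smooth = csp.smooth_profile(noisy, lags)
        rmse_smooth = np.sqrt(((smooth - truth) ** 2).mean())
        rmse_raw = np.sqrt(((noisy - truth) ** 2).mean())
        assert rmse_smooth < rmse_raw

    def test_basis_dim_too_large(self):
        with pytest.raises(pc.ValidationError, match="basis_dim"):
            csp.smooth_profile(np.zeros(30), basis_dim=30)

    def test_agrees_with_mgcv_on_clean_curve(self, tmp_path):
        """Independent oracle: mgcv's P-spline GAM on a noiseless curve."""
        lags = np.arange(1.0, 201.0)
        y = np.cos(lags / 25.0)
        ours = csp.smooth_profile(y, lags, basis_dim=40)
        datafile = tmp_path / "d.csv"
        outfile = tmp_path / "fit.csv"
        np.savetxt(datafile, np.column_stack([lags, y]), delimiter=",",
                   header="x,y", comments="")
        script = tmp_path / "s.R"
        script.write_text(textwrap.dedent(f"""
            library(mgcv)
            d <- read.csv("{datafile}")
            fit <- gam(y ~ s(x, k = 40, bs = "ps"), data = d)
            write.csv(data.frame(f = fitted(fit)), "{outfile}", row.names = FALSE)
        """))
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        theirs = np.loadtxt(outfile, skiprows=1)
        # both smoothers should essentially reproduce a clean smooth curve
        assert np.sqrt(((ours - theirs) ** 2).mean()) < 0.02


class TestExtractCriticalWindow:
    def _planted_profiles(self):
        lags = np.arange(1, 366)
        coef = np.where((lags >= 40) & (lags <= 80), -5.0, 0.0)
        r2 = np.where((lags >= 40) & (lags <= 80), 0.8, 0.05)
        return lags, coef, r2

    def test_planted_profile_exact(self):
        lags, coef, r2 = self._planted_profiles()
        window, coef_thr, r2_thr, tail = csp.extract_critical_window(lags, coef, r2)
        assert (window.open, window.close) == (80, 40)
        assert tail == "lower"
        # thresholds agree with direct quantile arithmetic on the profiles
        assert coef_thr == np.quantile(coef, 0.025)
        assert r2_thr == np.quantile(r2, 0.975)

    def test_thresholds_match_independent_quantile_routine(self):
        """Type-7 empirical quantiles recomputed by hand interpolation."""
        lags, coef, r2 = self._planted_profiles()
        rng = np.random.default_rng(2)
        coef = coef + rng.normal(0, 0.2, len(coef))
        r2 = np.clip(r2 + rng.normal(0, 0.02, len(r2)), 0, 1)
        _, coef_thr, r2_thr, _ = csp.extract_critical_window(lags, coef, r2)

        def quantile_type7(v, q):
            v = np.sort(v)
            h = (len(v) - 1) * q
            lo = int(np.floor(h))
            return v[lo] + (h - lo) * (v[min(lo + 1, len(v) - 1)] - v[lo])

        assert coef_thr == pytest.approx(quantile_type7(coef, 0.025), abs=1e-12)
        assert r2_thr == pytest.approx(quantile_type7(r2, 0.975), abs=1e-12)

    def test_flat_profiles_rejected(self):
        lags = np.arange(1, 366)
        with pytest.raises(csp.EmptyWindowError):
            csp.extract_critical_window(lags, np.zeros(365), np.zeros(365))

    def test_positive_effect_uses_upper_tail(self):
        lags, coef, r2 = self._planted_profiles()
        window, _, _, tail = csp.extract_critical_window(lags, -coef, r2)
        assert tail == "upper"
        assert (window.open, window.close) == (80, 40)

    def test_shift_invariance_to_constant_temperature(self, scenario):
        """Adding a constant to all temperatures leaves the window alone."""
        climate, pheno, _ = scenario
        m = pc.build_climate_matrix(climate, pheno.years, include_reference_day=False)
        prof1 = csp.compute_profile(pheno, m)
        shifted = pc.ClimateMatrix(m.years, m.lags, m.values + 5.0, m.reference_day)
        prof2 = csp.compute_profile(pheno, shifted)
        assert np.allclose(prof1.coef, prof2.coef, atol=1e-8)
        assert (prof1.critical.open, prof1.critical.close) == (
            prof2.critical.open, prof2.critical.close,
        )


class TestCueModel:
    def test_swa_window_gives_identical_fit(self, scenario, scenario_matrix):
        """Same window + statistic -> same computation path as the SWA."""
        _, pheno, _ = scenario
        res = sw.search_absolute(pheno, scenario_matrix, ("mean",), 120)
        best = res.best
        model = csp.fit_csp_cue(pheno, scenario_matrix, best.window)
        assert model.fit.slope == pytest.approx(best.fit.slope, rel=1e-9)
        assert model.fit.r2_adj == pytest.approx(best.fit.r2_adj, rel=1e-9)

    def test_zero_noise_planted_window_near_perfect(self):
        climate = pc.simulate_climate(pc.ClimateGenSpec(seed=60))
        spec = pc.PhenoGenSpec(
            window=sw.WindowSpec(60, 30, "absolute", "mean"),
            noise_sd=0.0, seed=61,
        )
        pheno, _ = pc.simulate_phenology(climate, spec, years=np.arange(1961, 2011))
        m = pc.build_climate_matrix(climate, pheno.years)
        model = csp.fit_csp_cue(pheno, m, sw.WindowSpec(60, 30, "absolute", "mean"))
        assert model.fit.r2 > 0.99  # whole-day rounding is the only noise

    def test_planted_window_containment(self):
        """The extracted critical window falls inside the planted window.

        The 2.5%/97.5% quantile rule admits only ~9 of 365 lags, so the
        extracted window is a narrow slice of the sensitive period; its
        location within the planted plateau varies, but it should lie
        inside it in nearly all replicates."""
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            climate = pc.simulate_climate(pc.ClimateGenSpec(seed=100 + seed))
            pheno, _ = pc.simulate_phenology(
                climate, pc.PhenoGenSpec(noise_sd=2.0, seed=200 + seed),
                years=np.arange(1961, 2011),
            )
            m = pc.build_climate_matrix(
                climate, pheno.years, include_reference_day=False
            )
            prof = csp.compute_profile(pheno, m)
            w = prof.critical
            hits += (w.close >= 14) and (w.open <= 81)
        assert hits >= int(0.7 * n_seeds)
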