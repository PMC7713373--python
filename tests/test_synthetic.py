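"""Synthetic-data generator: determinism, conservation, moment recovery."""

import numpy as np
import pandas as pd
import pytest

import droughtmort as dm


class TestClimate:
    def test_deterministic_given_seed(self):
        cfg = dm.TruthConfig(n_cells=10, n_years=5, seed=77)
        a = dm.generate_climate(cfg)
        b = dm.generate_climate(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_noise_flat_cycle_repeats_every_year(self):
        cp = dm.ClimateParams(temp_noise_sd=0.0, precip_noise_sd=0.0,
                              cell_temp_sd=0.0, cell_precip_sd=0.0)
        cfg = dm.TruthConfig(n_cells=3, n_years=4, seed=1, climate_params=cp)
        clim = dm.generate_climate(cfg)
        for _, grp in clim.groupby("cell_id"):
            mat = grp.sort_values(["year", "month"])["temperature"].to_numpy()
            mat = mat.reshape(-1, 12)
            assert np.allclose(mat, mat[0])

    def test_monthly_autocorrelation_matches_ar1(self):
        cp = dm.ClimateParams(temp_seasonal_amplitude=0.0, autocorr=0.5,
                              cell_temp_sd=0.0)
        cfg = dm.TruthConfig(n_cells=100, n_years=30, seed=4, climate_params=cp)
        clim = dm.generate_climate(cfg)
        acs = []
        for _, grp in clim.groupby("cell_id"):
            t = grp.sort_values(["year", "month"])["temperature"].to_numpy()
            anom = t - t.mean()
            acs.append(np.corrcoef(anom[:-1], anom[1:])[0, 1])
        # closed-form AR(1) lag-1 autocorrelation is phi = 0.5; the pooled
        # estimate over 100 cells x 372 months has SE ~ sqrt((1-phi^2)/n)/10
        assert np.mean(acs) == pytest.approx(0.5, abs=0.02)

    def test_precipitation_nonnegative_and_seasonal(self):
        cfg = dm.TruthConfig(n_cells=20, n_years=10, seed=2)
        clim = dm.generate_climate(cfg)
        assert (clim["precipitation"] >= 0).all()
        by_month = clim.groupby("month")["temperature"].mean()
        assert by_month.loc[7] > by_month.loc[1]  # summer peak present

    def test_spinup_year_included(self):
        cfg = dm.TruthConfig(n_cells=2, n_years=3, start_year=1990, seed=0)
        clim = dm.generate_climate(cfg)
        assert clim["year"].min() == 1989
        assert set(clim.loc[clim["year"] == 1989, "month"]) == set(range(1, 13))

    def test_negative_noise_sd_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            dm.ClimateParams(temp_noise_sd=-1.0).validate()


class TestMortality:
    def test_deterministic_given_seed(self):
        cfg = dm.TruthConfig(n_cells=15, n_years=6, seed=13)
        z = dm.standard_normal_cwb(cfg)
        a = dm.generate_mortality(cfg, z)
        b = dm.generate_mortality(cfg, z)
        pd.testing.assert_frame_equal(a.mortality_panel, b.mortality_panel)
        assert np.array_equal(a.truth["alpha_i"], b.truth["alpha_i"])

    def test_counts_never_exceed_forest(self, small_dataset):
        p = small_dataset.mortality_panel
        assert (p["mortality_pixels"] <= p["forest_pixels"]).all()
        assert (p["mortality_pixels"] >= 0).all()

    def test_null_generative_model_reproduces_trend(self):
        tiny = 1e-12
        cfg = dm.TruthConfig(
            n_cells=30, n_years=10, seed=6, beta0=0.0, alpha0=0.0,
            sigma2_alpha_i=tiny, sigma2_beta_i=tiny, sigma2_alpha_t=tiny,
            sigma2_beta_t=tiny, sigma2_mort=tiny, lam=1e6,
        )
        z = dm.standard_normal_cwb(cfg)
        ds = dm.generate_mortality(cfg, z)
        rate = ds.mortality_panel["mortality_pixels"] / cfg.pixels_per_cell
        trend = ds.truth["trend_rate"]
        # binomial noise only: standardized residuals ~ N(0, 1)
        zres = (rate - trend) / np.sqrt(trend * (1 - trend) / cfg.pixels_per_cell)
        assert abs(zres.mean()) < 0.15
        assert zres.std() == pytest.approx(1.0, abs=0.15)

    def test_population_slope_recovered_by_regression(self):
        cfg = dm.TruthConfig(n_cells=200, n_years=30, seed=8)  # beta0 = -1.88
        z = dm.standard_normal_cwb(cfg)
        ds = dm.generate_mortality(cfg, z)
        mf = ds.model_frame("truth")
        X = np.column_stack([np.ones(len(mf)), mf["cwb_z"]])
        coef, *_ = np.linalg.lstsq(X, mf["mort"], rcond=None)
        resid = mf["mort"] - X @ coef
        se = np.sqrt(resid.var() / (len(mf) * mf["cwb_z"].var()))
        # the OLS interval must cover the generating slope (allowing for the
        # extra spread from crossed random slopes)
        assert coef[1] == pytest.approx(-1.88, abs=max(4 * se, 0.15))

    def test_hinge_flat_above_kink_leaves_mean_at_intercept(self):
        cfg = dm.TruthConfig(
            n_cells=400, n_years=10, seed=10, response_shape="hinge",
            beta0=0.0, hinge_location=-1.6, hinge_slope_below=-2.0, alpha0=0.01,
        )
        z = dm.standard_normal_cwb(cfg)
        ds = dm.generate_mortality(cfg, z)
        mf = ds.model_frame("truth")
        above = mf.loc[mf["cwb_z"] > -1.6, "mort"]
        below = mf.loc[mf["cwb_z"] < -2.1, "mort"]
        # centered noise: mean above the kink is alpha0; below it is elevated
        se = above.std() / np.sqrt(len(above) / 40)
        assert abs(above.mean() - cfg.alpha0) < 3 * se
        assert below.mean() > above.mean() + 0.3

    def test_realized_intercept_variance_matches_config(self):
        cfg = dm.TruthConfig(n_cells=1500, n_years=3, seed=14)
        z = dm.standard_normal_cwb(cfg)
        ds = dm.generate_mortality(cfg, z)
        var = ds.truth["alpha_i"].var(ddof=1)
        # chi-square Monte-Carlo band for n = 1500 draws
        assert var == pytest.approx(cfg.sigma2_alpha_i, rel=0.12)

    def test_incomplete_cwb_panel_rejected(self):
        cfg = dm.TruthConfig(n_cells=5, n_years=5, seed=0)
        z = dm.standard_normal_cwb(cfg).iloc[:-3]
        with pytest.raises(ValueError, match="cover"):
            dm.generate_mortality(cfg, z)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            dm.TruthConfig(n_years=2)
        with pytest.raises(ValueError):
            dm.TruthConfig(sigma2_mort=0.0)
        with pytest.raises(ValueError):
            dm.TruthConfig(rho_i=1.0)
        with pytest.raises(ValueError):
            dm.TruthConfig(response_shape="hinge", hinge_slope_below=0.5)
        with pytest.raises(ValueError):
            dm.TruthConfig(pixels_per_cell=0)


def test_full_route_attaches_climate_and_recovers_window():
    cfg = dm.TruthConfig(n_cells=12, n_years=8, seed=5)
    ds = dm.generate_dataset(cfg)
    assert ds.climate_panel is not None
    assert set(ds.cwb_z["year"]) == set(cfg.years())
    mf = ds.model_frame("panel")
    assert {"cell_id", "year", "mort", "cwb_z"} <= set(mf.columns)
    assert len(mf) == 12 * 8
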