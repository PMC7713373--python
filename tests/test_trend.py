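"""Cell exclusion, per-cell logistic trends, fractional deviation."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import droughtmort as dm


def _panel(n_cells, years, forest=1000, dead=None):
    rows = []
    for c in range(n_cells):
        for i, y in enumerate(years):
            rows.append({
                "cell_id": c, "year": y, "forest_pixels": forest,
                "mortality_pixels": 0 if dead is None else dead[i],
            })
    return pd.DataFrame(rows)


class TestExclusion:
    def test_flagged_cells_removed(self):
        panel = _panel(3113, [2000])
        mask = pd.Series(False, index=np.arange(3113))
        mask.iloc[:200] = True
        out = dm.exclude_nonforest_cells(panel, mask)
        assert out["cell_id"].nunique() == 2913

    def test_empty_mask_is_identity(self):
        panel = _panel(5, [2000, 2001])
        mask = pd.Series(False, index=np.arange(5))
        out = dm.exclude_nonforest_cells(panel, mask)
        pd.testing.assert_frame_equal(out, panel)

    def test_all_flagged_warns_and_empties(self):
        panel = _panel(4, [2000])
        mask = pd.Series(True, index=np.arange(4))
        with pytest.warns(UserWarning, match="all cells"):
            out = dm.exclude_nonforest_cells(panel, mask)
        assert out.empty

    def test_uncovered_cells_error(self):
        panel = _panel(5, [2000])
        mask = pd.Series(False, index=np.arange(3))
        with pytest.raises(ValueError, match="mask does not cover"):
            dm.exclude_nonforest_cells(panel, mask)


def _grid_search_oracle(years, dead, forest):
    """Independent coarse grid search of the binomial log-likelihood."""
    yc = years - years.mean()
    best, arg = -np.inf, None
    for b0 in np.linspace(-8, -1, 141):
        for b1 in np.linspace(-0.3, 0.3, 121):
            p = expit(b0 + b1 * yc)
            ll = np.sum(dead * np.log(p) + (forest - dead) * np.log1p(-p))
            if ll > best:
                best, arg = ll, (b0, b1)
    return arg


class TestTrendFit:
    def test_constant_rate_gives_zero_slope(self):
        years = np.arange(1990, 2000)
        df = pd.DataFrame({"cell_id": 0, "year": years,
                           "forest_pixels": 1000, "mortality_pixels": 50})
        fit = dm.fit_trend(df)
        assert fit.converged
        assert fit.slope == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(fit.fitted_rate, 0.05, atol=1e-9)

    def test_recovers_logit_linear_series_vs_grid_oracle(self):
        rng = np.random.default_rng(3)
        years = np.arange(1987, 2017)
        rate = expit(-4.5 + 0.05 * (years - years.mean()))
        dead = rng.binomial(5000, rate)
        df = pd.DataFrame({"cell_id": 0, "year": years,
                           "forest_pixels": 5000, "mortality_pixels": dead})
        fit = dm.fit_trend(df)
        b0, b1 = _grid_search_oracle(years.astype(float), dead, 5000)
        assert fit.converged
        assert fit.intercept == pytest.approx(b0, abs=0.05)
        assert fit.slope == pytest.approx(b1, abs=0.005)

    def test_slope_coverage_over_replicates(self):
        # the ML interval should cover the generating slope in >= 90% of runs
        rng = np.random.default_rng(12)
        years = np.arange(1987, 2017)
        true_slope = 0.04
        hits = 0
        n_rep = 40
        for _ in range(n_rep):
            rate = expit(-4.0 + true_slope * (years - years.mean()))
            dead = rng.binomial(3000, rate)
            df = pd.DataFrame({"cell_id": 0, "year": years,
                               "forest_pixels": 3000, "mortality_pixels": dead})
            fit = dm.fit_trend(df)
            # asymptotic 95% interval from the binomial information
            import statsmodels.api as sm

            X = sm.add_constant(years - years.mean())
            res = sm.GLM(np.column_stack([dead, 3000 - dead]), X,
                         family=sm.families.Binomial()).fit()
            lo, hi = res.conf_int()[1]
            hits += lo <= true_slope <= hi
        assert hits / n_rep >= 0.9

    def test_all_zero_mortality_uses_fallback(self):
        years = np.arange(2000, 2010)
        df = pd.DataFrame({"cell_id": 7, "year": years,
                           "forest_pixels": 1000, "mortality_pixels": 0})
        fit = dm.fit_trend(df)
        assert not fit.converged
        expected = 0.5 / (10 * 1000 + 1)
        assert np.allclose(fit.fitted_rate, expected)

    def test_too_short_series_rejected(self):
        df = pd.DataFrame({"cell_id": 0, "year": [2000, 2001],
                           "forest_pixels": 100, "mortality_pixels": 1})
        with pytest.raises(ValueError, match="3 years"):
            dm.fit_trend(df)

    def test_pearson_residuals_sum_to_zero(self):
        rng = np.random.default_rng(5)
        years = np.arange(1990, 2015)
        rate = expit(-4.0 + 0.03 * (years - years.mean()))
        dead = rng.binomial(2000, rate)
        df = pd.DataFrame({"cell_id": 0, "year": years,
                           "forest_pixels": 2000, "mortality_pixels": dead})
        fit = dm.fit_trend(df)
        obs = dead / 2000
        pearson = (obs - fit.fitted_rate) / np.sqrt(
            fit.fitted_rate * (1 - fit.fitted_rate) / 2000
        )
        # score equation of the intercept: weighted residual sum vanishes
        w = np.sqrt(2000 * fit.fitted_rate * (1 - fit.fitted_rate))
        assert np.sum(pearson * w) == pytest.approx(0.0, abs=1e-4)


class TestFractionalDeviation:
    def test_anchor_values(self):
        assert dm.fractional_deviation(0.01, 0.01) == 0.0
        assert dm.fractional_deviation(0.02, 0.01) == 1.0  # doubling = +100%
        assert dm.fractional_deviation(0.0, 0.01) == -1.0

    def test_nonpositive_fitted_rate_rejected(self):
        with pytest.raises(ValueError, match="fallback"):
            dm.fractional_deviation(0.01, 0.0)

    def test_scale_free_in_pixel_counts(self, small_dataset):
        panel = small_dataset.mortality_panel
        dev1 = dm.deviation_panel(panel)
        scaled = panel.assign(
            forest_pixels=panel["forest_pixels"] * 13,
            mortality_pixels=panel["mortality_pixels"] * 13,
        )
        dev2 = dm.deviation_panel(scaled)
        assert np.allclose(dev1["mort"], dev2["mort"], atol=1e-9)

    def test_centered_near_zero_without_signal(self):
        # beta0 = 0 and mean-zero noise: deviations average ~ alpha0
        cfg = dm.TruthConfig(n_cells=150, n_years=25, seed=9, beta0=0.0,
                             alpha0=0.0)
        z = dm.standard_normal_cwb(cfg)
        ds = dm.generate_mortality(cfg, z)
        mort = ds.truth["deviations"]["mort"]
        se = mort.std() / np.sqrt(len(mort) / 25)  # year effects shared
        assert abs(mort.mean()) < 3 * max(se, 0.08)
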