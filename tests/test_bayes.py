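"""Hierarchical Bayesian fit: bookkeeping, recovery, limits, comparison."""

import warnings

import numpy as np
import pandas as pd
import pytest

import droughtmort as dm
from droughtmort.bayes import ConvergenceError, _check_convergence


def _quiet_fit(frame, spec, rhat_action="ignore"):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return dm.fit_bayes(frame, spec, rhat_action=rhat_action)


class TestBookkeeping:
    def test_default_spec_pools_8000_draws(self):
        spec = dm.ModelSpec()
        assert (spec.chains, spec.iterations, spec.warmup) == (4, 4000, 2000)
        assert spec.n_draws == 8000

    def test_draw_count_is_chains_times_kept(self, small_dataset):
        spec = dm.ModelSpec(variant="linear", chains=3, iterations=80,
                            warmup=30, seed=2, compute_loglik=False)
        post = _quiet_fit(small_dataset.model_frame("truth"), spec)
        assert post.n_draws == 3 * 50
        assert post.draws["alpha0"].shape == (3, 50)
        assert post.stacked("beta0").shape == (150,)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            dm.ModelSpec(variant="quadratic")
        with pytest.raises(ValueError):
            dm.ModelSpec(warmup=4000, iterations=4000)
        with pytest.raises(ValueError):
            dm.ModelSpec(variant="smooth", smooth_k=2)

    def test_rhat_reported_for_every_parameter(self, small_posterior):
        idx = small_posterior.rhat.index
        for name in ("alpha0", "beta0", "sigma2_mort", "lam",
                     "sigma2_alpha_i", "rho_t"):
            assert name in idx
        assert any(i.startswith("alpha_i[") for i in idx)


class TestRecovery:
    def test_population_and_family_parameters(self, small_posterior):
        # data generated at the default truth; 60 cells x 20 years
        s = small_posterior.summary()
        truth = {"beta0": -1.88, "sigma2_mort": 0.13, "lam": 0.53,
                 "sigma2_alpha_i": 0.18}
        for name, v in truth.items():
            m, sd = s.loc[name, "mean"], s.loc[name, "sd"]
            assert abs(m - v) <= max(0.15 * abs(v), 3 * sd), name

    def test_posterior_predictive_mean_equals_linear_predictor(
            self, small_posterior, rng):
        # the exGaussian error is centered: E[mort | z] is alpha0 + beta0 z
        from droughtmort.threshold import predictive_draws

        grid = np.array([-2.0, 0.0, 2.0])
        draws = predictive_draws(small_posterior, grid, rng)
        a = small_posterior.stacked("alpha0").mean()
        b = small_posterior.stacked("beta0").mean()
        se = draws.std(axis=0) / np.sqrt(draws.shape[0])
        assert np.allclose(draws.mean(axis=0), a + b * grid, atol=4 * se + 0.02)


class TestGaussianLimit:
    def test_fixed_large_rate_matches_gaussian_ml(self):
        rng = np.random.default_rng(17)
        n_cells, n_years = 40, 12
        ci = np.repeat(np.arange(n_cells), n_years)
        yi = np.tile(np.arange(n_years), n_cells)
        x = rng.standard_normal(len(ci))
        y = (0.2 + rng.normal(0, 0.3, n_cells)[ci] + rng.normal(0, 0.2, n_years)[yi]
             + (-1.2 + rng.normal(0, 0.15, n_cells)[ci]) * x
             + rng.normal(0, 0.5, len(ci)))
        frame = pd.DataFrame({"cell_id": ci, "year": yi, "mort": y, "cwb_z": x})
        ml = dm.fit_gaussian_mixed(y, x, ci, yi)
        spec = dm.ModelSpec(variant="linear", error_family="exgaussian",
                            fix_lam=1e4, chains=2, iterations=800, warmup=400,
                            seed=3, compute_loglik=False)
        post = _quiet_fit(frame, spec)
        s = post.summary()
        assert s.loc["beta0", "mean"] == pytest.approx(
            ml.beta0, abs=3 * s.loc["beta0", "sd"])
        assert s.loc["sigma2_mort", "mean"] == pytest.approx(ml.sigma2, rel=0.2)


@pytest.fixture(scope="module")
def hinge_frame():
    cfg = dm.TruthConfig(n_cells=60, n_years=15, seed=23,
                         response_shape="hinge", beta0=0.0,
                         hinge_location=-1.0, hinge_slope_below=-2.5)
    z = dm.standard_normal_cwb(cfg)
    return dm.generate_mortality(cfg, z).model_frame("truth")


class TestModelComparison:
    def test_model_compared_with_itself_has_zero_delta(self, small_posterior):
        table = dm.compare_models({"a": small_posterior, "b": small_posterior})
        assert table["elpd_diff"].abs().max() == pytest.approx(0.0, abs=1e-6)

    def test_smooth_beats_linear_on_hinge_data(self, hinge_frame):
        kw = dict(chains=2, iterations=700, warmup=350, seed=31)
        linear = _quiet_fit(hinge_frame, dm.ModelSpec(variant="linear", **kw))
        smooth = _quiet_fit(hinge_frame, dm.ModelSpec(variant="smooth", **kw))
        table = dm.compare_models({"linear": linear, "smooth": smooth})
        assert table.index[0] == "smooth"
        d = table.loc["linear", "elpd_diff"]
        se = table.loc["linear", "dse"]
        assert d > 2 * se

    def test_null_competitive_on_pure_noise(self):
        rng = np.random.default_rng(29)
        n_cells, n_years = 40, 12
        ci = np.repeat(np.arange(n_cells), n_years)
        yi = np.tile(np.arange(n_years), n_cells)
        y = (rng.normal(0, 0.4, n_cells)[ci] + rng.normal(0, 0.3, n_years)[yi]
             + rng.normal(0, 0.6, len(ci)))
        frame = pd.DataFrame({"cell_id": ci, "year": yi, "mort": y,
                              "cwb_z": rng.standard_normal(len(ci))})
        kw = dict(chains=2, iterations=700, warmup=350, seed=37,
                  error_family="gaussian")
        null = _quiet_fit(frame, dm.ModelSpec(variant="null", **kw))
        linear = _quiet_fit(frame, dm.ModelSpec(variant="linear", **kw))
        table = dm.compare_models({"null": null, "linear": linear})
        # with no CWB signal the null model must be within 2 SE of the best
        # (it is usually the best outright)
        assert table.loc["null", "elpd_diff"] <= 2 * max(
            table.loc["null", "dse"], 1.0)


class TestDiagnosticsAndIO:
    def test_convergence_gate_raises_on_bad_core_rhat(self, small_posterior):
        import copy

        bad = copy.copy(small_posterior)
        bad.rhat = pd.Series({"beta0": 1.5, "alpha0": 1.0})
        with pytest.raises(ConvergenceError, match="beta0"):
            _check_convergence(bad, "raise")
        _check_convergence(bad, "ignore")  # no error

    def test_posterior_roundtrip(self, small_posterior, tmp_path):
        path = tmp_path / "post.npz"
        small_posterior.save(path)
        back = dm.load_posterior(path)
        assert back.spec == small_posterior.spec
        assert back.n_draws == small_posterior.n_draws
        for k, v in small_posterior.draws.items():
            assert np.array_equal(v, back.draws[k], equal_nan=True)
        pd.testing.assert_frame_equal(back.summary(), small_posterior.summary())

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            dm.fit_bayes(pd.DataFrame({"cell_id": [1], "year": [2000]}),
                         dm.ModelSpec(variant="linear"))

    def test_nonfinite_response_rejected(self):
        frame = pd.DataFrame({"cell_id": [0, 0, 1], "year": [0, 1, 0],
                              "mort": [0.1, np.nan, 0.2], "cwb_z": [0.0, 1, 2]})
        with pytest.raises(ValueError, match="non-finite"):
            dm.fit_bayes(frame, dm.ModelSpec(variant="linear"))
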