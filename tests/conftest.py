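import warnings

import numpy as np
import pytest

import droughtmort as dm


@pytest.fixture(scope="session")
def small_dataset():
    """60 cells x 20 years, default (Table-1-style) truth, direct z route."""
    cfg = dm.TruthConfig(n_cells=60, n_years=20, seed=11)
    z = dm.standard_normal_cwb(cfg)
    return dm.generate_mortality(cfg, z)


@pytest.fixture(scope="session")
def small_posterior(small_dataset):
    """Short exGaussian linear fit of the small dataset's truth deviations."""
    spec = dm.ModelSpec(variant="linear", error_family="exgaussian",
                        chains=2, iterations=600, warmup=300, seed=5)
    mf = small_dataset.model_frame("truth")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return dm.fit_bayes(mf, spec, rhat_action="ignore")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def constant_posterior(alpha0=0.0, beta0=-1.0, sigma2=0.25, lam=None,
                       n_draws=4000, chains=2):
    """Hand-built ModelPosterior with all draws pinned to fixed values.

    Gives closed-form predictive distributions for the probability-curve
    checks without running MCMC.  Variance components are set to ~0 so the
    only predictive noise is the residual.
    """
    kept = n_draws // chains
    tiny = 1e-12

    def c(v):
        return np.full((chains, kept), v)

    draws = {
        "alpha0": c(alpha0), "beta0": c(beta0), "sigma2_mort": c(sigma2),
        "lam": c(lam if lam is not None else np.nan),
        "sigma2_alpha_i": c(tiny), "sigma2_beta_i": c(tiny), "rho_i": c(0.0),
        "sigma2_alpha_t": c(tiny), "sigma2_beta_t": c(tiny), "rho_t": c(0.0),
        "sigma2_smooth": c(np.nan),
    }
    spec = dm.ModelSpec(variant="linear", error_family="exgaussian",
                        chains=chains, iterations=2 * kept, warmup=kept)
    import pandas as pd

    return dm.ModelPosterior(spec=spec, draws=draws, rhat=pd.Series(dtype=float),
                             basis=None, loglik=None, y_sd=1.0, n_obs=0)
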