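"""Bayesian hierarchical drought-response model with exGaussian errors.

The response model predicts the fractional deviation in canopy mortality,
``mort_it``, from the z-scored climatic water balance ``z_it``:

    mort_it = (alpha0 + alpha_i + alpha_t) + (beta0 + beta_i + beta_t) z_it
              [+ f(z_it)]                                      (smooth variant)
              + eps_it

    (alpha_i, beta_i) ~ MVN(0, Sigma_i)   crossed cell effects
    (alpha_t, beta_t) ~ MVN(0, Sigma_t)   crossed year effects
    f(z) = sum_j B_j(z) gamma_j,  gamma_j ~ N(0, sigma2_smooth)
    eps_it ~ exGaussian with Gaussian variance sigma2_mort and exponential
             rate lambda, centered to mean zero

The exGaussian error (Gaussian + exponential convolution) gives the model a
heavy right tail for the rare cell-years with extreme excess mortality.  The
error is centered so that E[mort_it] equals the linear predictor (the
exponential component's mean 1/lambda is subtracted), matching the
mean-parameterized exGaussian regression family used in applied practice;
fractional deviations from a fitted trend must average near zero, which the
uncentered convolution cannot do.

Inference is a blocked Gibbs sampler with Metropolis steps for the variance
parameters.  The exGaussian likelihood is handled by data augmentation: the
latent exponential component e_it has a lower-truncated-normal full
conditional, and conditional on e the model is linear-Gaussian, so fixed
effects, smooth weights and both crossed random-effect blocks have exact
multivariate-normal updates.  Convergence is monitored with rank-normalized
split R-hat; model comparison uses PSIS-LOO (both via arviz).

Priors (weakly regularizing, scaled by sd(y)): Normal(0, (2.5 sd(y))^2) on
alpha0/beta0, half-Student-t(3, 0, 2.5 sd(y)) on all standard deviations,
uniform (LKJ(1)) on correlations, Exponential(mean sd(y)) on 1/lambda.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .exgauss import exgaussian_logpdf
from .splines import thin_plate_basis

log = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "ModelPosterior",
    "ConvergenceError",
    "fit_bayes",
    "compare_models",
    "load_posterior",
]

_SCALARS = [
    "alpha0", "beta0", "sigma2_mort", "lam",
    "sigma2_alpha_i", "sigma2_beta_i", "rho_i",
    "sigma2_alpha_t", "sigma2_beta_t", "rho_t",
    "sigma2_smooth",
]


class ConvergenceError(RuntimeError):
    """Raised when MCMC chains fail the R-hat convergence gate."""


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of one model fit.

    ``variant``: 'null' (random intercepts only), 'linear' (adds the
    population and random CWB slopes) or 'smooth' (adds the rank-k thin-plate
    smooth on top of the linear term).  ``error_family`` is 'gaussian' or
    'exgaussian'; ``fix_lam`` pins the exponential rate instead of sampling
    it (useful for Gaussian-limit checks).
    """

    variant: str = "smooth"
    error_family: str = "exgaussian"
    smooth_k: int = 10
    month: int | None = None
    window: int | None = None
    chains: int = 4
    iterations: int = 4000
    warmup: int = 2000
    seed: int = 0
    fix_lam: float | None = None
    compute_loglik: bool = True

    def __post_init__(self):
        if self.variant not in ("null", "linear", "smooth"):
            raise ValueError("variant must be null, linear or smooth")
        if self.error_family not in ("gaussian", "exgaussian"):
            raise ValueError("error_family must be gaussian or exgaussian")
        if self.variant == "smooth" and self.smooth_k < 3:
            raise ValueError("smooth_k must be >= 3")
        if not 0 < self.warmup < self.iterations:
            raise ValueError("need 0 < warmup < iterations")
        if self.chains < 1:
            raise ValueError("need at least one chain")

    @property
    def n_draws(self):
        """Pooled post-warmup draw count = chains * (iterations - warmup)."""
        return self.chains * (self.iterations - self.warmup)


@dataclass
class ModelPosterior:
    """Joint posterior draws of the hierarchical model plus diagnostics."""

    spec: ModelSpec
    draws: dict  # name -> array (chains, kept_draws[, dim])
    rhat: pd.Series
    basis: object | None  # ThinPlateBasis for the smooth variant
    loglik: np.ndarray | None  # (chains, kept, n_obs) pointwise log-likelihood
    y_sd: float
    n_obs: int

    @property
    def n_draws(self):
        a = self.draws["alpha0"]
        return a.shape[0] * a.shape[1]

    def stacked(self, name):
        """Draws of ``name`` pooled over chains, shape (n_draws, ...)."""
        d = self.draws[name]
        return d.reshape(-1, *d.shape[2:])

    def to_inferencedata(self):
        import arviz as az

        post = {k: v for k, v in self.draws.items()}
        kwargs = {}
        if self.loglik is not None:
            kwargs["log_likelihood"] = {"mort": self.loglik}
        return az.from_dict(posterior=post, **kwargs)

    def summary(self) -> pd.DataFrame:
        """Posterior mean, SD, central 95% interval and R-hat per parameter."""
        rows = []
        for name in _SCALARS:
            if name not in self.draws:
                continue
            s = self.stacked(name)
            if np.all(np.isnan(s)):
                continue  # parameter not part of this variant/family
            rows.append(
                {
                    "parameter": name,
                    "mean": s.mean(),
                    "sd": s.std(ddof=1),
                    "q2.5": np.quantile(s, 0.025),
                    "q97.5": np.quantile(s, 0.975),
                    "rhat": self.rhat.get(name, np.nan),
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    def loo(self):
        """PSIS-LOO expected log predictive density (requires stored loglik)."""
        import arviz as az

        if self.loglik is None:
            raise ValueError("fit was run with compute_loglik=False")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return az.loo(self.to_inferencedata(), pointwise=True)

    def save(self, path):
        """Persist draws, spec and spline basis to a ``.npz`` container."""
        import dataclasses
        import json

        payload = {f"draw_{k}": v for k, v in self.draws.items()}
        payload["spec_json"] = np.array(
            json.dumps(dataclasses.asdict(self.spec))
        )
        payload["rhat_names"] = np.array(list(self.rhat.index))
        payload["rhat_values"] = self.rhat.to_numpy()
        payload["y_sd"] = np.array(self.y_sd)
        payload["n_obs"] = np.array(self.n_obs)
        if self.basis is not None:
            payload["basis_knots"] = self.basis.knots
            payload["basis_coef_map"] = self.basis.coef_map
            payload["basis_lin_adjust"] = self.basis.lin_adjust
        if self.loglik is not None:
            payload["loglik"] = self.loglik
        np.savez_compressed(path, **payload)


def load_posterior(path) -> "ModelPosterior":
    """Load a posterior saved with :meth:`ModelPosterior.save`."""
    import json

    from .splines import ThinPlateBasis

    with np.load(path, allow_pickle=False) as z:
        spec = ModelSpec(**json.loads(str(z["spec_json"])))
        draws = {k[5:]: z[k] for k in z.files if k.startswith("draw_")}
        rhat = pd.Series(z["rhat_values"], index=list(z["rhat_names"]))
        basis = None
        if "basis_knots" in z.files:
            basis = ThinPlateBasis(
                knots=z["basis_knots"],
                coef_map=z["basis_coef_map"],
                lin_adjust=z["basis_lin_adjust"],
            )
        loglik = z["loglik"] if "loglik" in z.files else None
        return ModelPosterior(
            spec=spec, draws=draws, rhat=rhat, basis=basis,
            loglik=loglik, y_sd=float(z["y_sd"]), n_obs=int(z["n_obs"]),
        )


def _half_t3_logpdf(s, scale):
    # half-Student-t(3, 0, scale) up to a constant
    return -2.0 * np.log1p(s**2 / (3.0 * scale**2))


def _trunc_norm_pos(mean, sd, rng):
    """Vectorized N(mean, sd^2) truncated to (0, inf); sd scalar."""
    mean = np.asarray(mean, dtype=float)
    a = -mean / sd  # standardized lower bound
    out = np.empty_like(mean)
    easy = a < 5.0
    if easy.any():
        lo = ndtr(a[easy])
        u = rng.random(easy.sum())
        p = np.minimum(lo + u * (1.0 - lo), 1.0 - 1e-16)
        out[easy] = mean[easy] + sd * ndtri(p)
    hard = ~easy
    if hard.any():
        ah = a[hard]
        x = np.empty(ah.size)
        todo = np.ones(ah.size, bool)
        while todo.any():  # shifted-exponential rejection (Robert 1995)
            at = ah[todo]
            prop = at + rng.exponential(1.0 / at)
            acc = rng.random(at.size) < np.exp(-0.5 * (prop - at) ** 2)
            hit = np.where(todo)[0][acc]
            x[hit] = prop[acc]
            todo[hit] = False
        out[hard] = mean[hard] + sd * x
    return np.maximum(out, 1e-300)


def _bivariate_normal_loglik(a, b, s2a, s2b, rho):
    """Sum of centered bivariate normal log-densities; summary-statistic form."""
    n = a.size
    sa, sb = np.sqrt(s2a), np.sqrt(s2b)
    om = 1.0 - rho**2
    qa = (a @ a) / s2a
    qb = (b @ b) / s2b
    qab = (a @ b) / (sa * sb)
    return -n * (np.log(2 * np.pi * sa * sb) + 0.5 * np.log(om)) - (
        qa - 2 * rho * qab + qb
    ) / (2 * om)


class _AdaptiveScale:
    """Scalar random-walk scale adapted toward a target acceptance rate."""

    def __init__(self, scale=0.3, target=0.35):
        self.scale = scale
        self.target = target
        self.accepted = 0
        self.tried = 0
        self.rounds = 0

    def record(self, accepted):
        self.tried += 1
        self.accepted += bool(accepted)

    def adapt(self):
        if self.tried == 0:
            return
        self.rounds += 1
        rate = self.accepted / self.tried
        step = 1.0 / np.sqrt(self.rounds)
        self.scale = float(np.clip(self.scale * np.exp(step * (rate - self.target)),
                                   1e-4, 10.0))
        self.accepted = self.tried = 0


def _chol2_sample(p11, p12, p22, l1, l2, rng):
    """Sample (u, v) ~ N(P^{-1} l, P^{-1}) for stacked 2x2 precisions (vectorized)."""
    det = p11 * p22 - p12**2
    v11 = p22 / det
    v12 = -p12 / det
    v22 = p11 / det
    m1 = v11 * l1 + v12 * l2
    m2 = v12 * l1 + v22 * l2
    c11 = np.sqrt(v11)
    c21 = v12 / c11
    c22 = np.sqrt(np.maximum(v22 - c21**2, 1e-300))
    z1 = rng.standard_normal(p11.shape)
    z2 = rng.standard_normal(p11.shape)
    return m1 + c11 * z1, m2 + c21 * z1 + c22 * z2


def _run_chain(y, x, B, cell_idx, year_idx, spec, rng, y_sd):
    n = y.size
    n_cells = cell_idx.max() + 1
    n_years = year_idx.max() + 1
    has_x = spec.variant in ("linear", "smooth")
    has_smooth = spec.variant == "smooth"
    exg = spec.error_family == "exgaussian"
    k = B.shape[1] if has_smooth else 0

    loc_sd = 2.5 * y_sd  # prior SD of alpha0 / beta0
    sd_scale = 2.5 * y_sd  # half-t scale for all SD parameters
    invlam_rate = 1.0 / y_sd  # Exponential prior on 1/lambda

    # fixed + smooth design
    cols = [np.ones(n)]
    if has_x:
        cols.append(x)
    if has_smooth:
        cols.append(B)
    F = np.column_stack(cols)
    FtF = F.T @ F
    p_fixed = 2 if has_x else 1

    # per-group design crossproducts (fixed across iterations)
    n_i = np.bincount(cell_idx, minlength=n_cells).astype(float)
    Sx_i = np.bincount(cell_idx, weights=x, minlength=n_cells)
    Sxx_i = np.bincount(cell_idx, weights=x * x, minlength=n_cells)
    n_t = np.bincount(year_idx, minlength=n_years).astype(float)
    Sx_t = np.bincount(year_idx, weights=x, minlength=n_years)
    Sxx_t = np.bincount(year_idx, weights=x * x, minlength=n_years)

    # initial state (overdispersed across chains through rng)
    alpha0 = y.mean() + 0.5 * y_sd * rng.standard_normal()
    beta0 = 0.5 * y_sd * rng.standard_normal() if has_x else 0.0
    gamma = 0.1 * rng.standard_normal(k) if has_smooth else np.zeros(0)
    a_i = np.zeros(n_cells)
    b_i = np.zeros(n_cells)
    a_t = np.zeros(n_years)
    b_t = np.zeros(n_years)
    sig2 = float(np.var(y) * np.exp(rng.normal(0, 0.3))) or y_sd**2
    lam = spec.fix_lam if spec.fix_lam is not None else float(
        np.exp(rng.normal(0, 0.3)) / y_sd
    )
    s_ai = s_at = 0.3 * y_sd * np.exp(rng.normal(0, 0.2))
    s_bi = s_bt = 0.3 * y_sd * np.exp(rng.normal(0, 0.2))
    rho_i = rho_t = 0.0
    s_smooth = y_sd
    e = np.full(n, 1.0 / lam) if exg else np.zeros(n)

    mh = {name: _AdaptiveScale() for name in
          ("sigma", "lam", "smooth",
           "sig_i_a", "sig_i_b", "rho_i", "sig_t_a", "sig_t_b", "rho_t")}

    kept = spec.iterations - spec.warmup
    store = {nm: np.empty(kept) for nm in
             ("alpha0", "beta0", "sigma2_mort", "lam",
              "sigma2_alpha_i", "sigma2_beta_i", "rho_i",
              "sigma2_alpha_t", "sigma2_beta_t", "rho_t", "sigma2_smooth")}
    store["alpha_i"] = np.empty((kept, n_cells))
    store["alpha_t"] = np.empty((kept, n_years))
    if has_x:
        store["beta_i"] = np.empty((kept, n_cells))
        store["beta_t"] = np.empty((kept, n_years))
    if has_smooth:
        store["gamma"] = np.empty((kept, k))
    ll_store = (np.empty((kept, n), dtype=np.float32)
                if (spec.compute_loglik) else None)

    def linpred():
        eta = F @ np.concatenate([[alpha0], [beta0] if has_x else [], gamma])
        eta = eta + a_i[cell_idx] + a_t[year_idx]
        if has_x:
            eta = eta + (b_i[cell_idx] + b_t[year_idx]) * x
        return eta

    eta = linpred()

    for it in range(spec.iterations):
        # ---- latent exponential component (auxiliary for the linear blocks;
        # resampled from its full conditional every iteration) ----
        if exg:
            r = y - eta + 1.0 / lam  # = e + nu
            e = _trunc_norm_pos(r - lam * sig2, np.sqrt(sig2), rng)
            yg = y + 1.0 / lam - e
        else:
            yg = y

        # ---- fixed effects + smooth weights (conjugate) ----
        rf = yg - a_i[cell_idx] - a_t[year_idx]
        if has_x:
            rf = rf - (b_i[cell_idx] + b_t[year_idx]) * x
        prior_prec = np.full(p_fixed + k, 1.0 / loc_sd**2)
        if has_smooth:
            prior_prec[p_fixed:] = 1.0 / s_smooth**2
        P = FtF / sig2 + np.diag(prior_prec)
        bvec = F.T @ rf / sig2
        L = np.linalg.cholesky(P)
        mean_f = np.linalg.solve(L.T, np.linalg.solve(L, bvec))
        theta_f = mean_f + np.linalg.solve(L.T, rng.standard_normal(p_fixed + k))
        alpha0 = theta_f[0]
        if has_x:
            beta0 = theta_f[1]
        if has_smooth:
            gamma = theta_f[p_fixed:]
        eta_f = F @ theta_f

        # ---- crossed cell effects ----
        rc = yg - eta_f - a_t[year_idx]
        if has_x:
            rc = rc - b_t[year_idx] * x
        Sr = np.bincount(cell_idx, weights=rc, minlength=n_cells)
        if has_x:
            Sxr = np.bincount(cell_idx, weights=rc * x, minlength=n_cells)
            om = 1.0 - rho_i**2
            ip11 = 1.0 / (s_ai**2 * om)
            ip22 = 1.0 / (s_bi**2 * om)
            ip12 = -rho_i / (s_ai * s_bi * om)
            a_i, b_i = _chol2_sample(
                ip11 + n_i / sig2, ip12 + Sx_i / sig2, ip22 + Sxx_i / sig2,
                Sr / sig2, Sxr / sig2, rng,
            )
        else:
            prec = 1.0 / s_ai**2 + n_i / sig2
            a_i = Sr / sig2 / prec + rng.standard_normal(n_cells) / np.sqrt(prec)

        # ---- crossed year effects ----
        rt = yg - eta_f - a_i[cell_idx]
        if has_x:
            rt = rt - b_i[cell_idx] * x
        Sr = np.bincount(year_idx, weights=rt, minlength=n_years)
        if has_x:
            Sxr = np.bincount(year_idx, weights=rt * x, minlength=n_years)
            om = 1.0 - rho_t**2
            ip11 = 1.0 / (s_at**2 * om)
            ip22 = 1.0 / (s_bt**2 * om)
            ip12 = -rho_t / (s_at * s_bt * om)
            a_t, b_t = _chol2_sample(
                ip11 + n_t / sig2, ip12 + Sx_t / sig2, ip22 + Sxx_t / sig2,
                Sr / sig2, Sxr / sig2, rng,
            )
        else:
            prec = 1.0 / s_at**2 + n_t / sig2
            a_t = Sr / sig2 / prec + rng.standard_normal(n_years) / np.sqrt(prec)

        # ---- recentering (interweaving): exact Gibbs move of the shared
        # mean between the population terms and each random-effect block ----
        def recenter(ua, ub, s_a, s_b, rho, mu_a, mu_b, with_slope):
            m = ua.size
            if with_slope:
                om = 1.0 - rho**2
                i11 = 1.0 / (s_a**2 * om)
                i22 = 1.0 / (s_b**2 * om)
                i12 = -rho / (s_a * s_b * om)
                p11 = m * i11 + 1.0 / loc_sd**2
                p22 = m * i22 + 1.0 / loc_sd**2
                p12 = m * i12
                l1 = i11 * ua.sum() + i12 * ub.sum() - mu_a / loc_sd**2
                l2 = i12 * ua.sum() + i22 * ub.sum() - mu_b / loc_sd**2
                ca, cb = _chol2_sample(np.atleast_1d(p11), np.atleast_1d(p12),
                                       np.atleast_1d(p22), np.atleast_1d(l1),
                                       np.atleast_1d(l2), rng)
                return float(ca[0]), float(cb[0])
            prec = m / s_a**2 + 1.0 / loc_sd**2
            mean = (ua.sum() / s_a**2 - mu_a / loc_sd**2) / prec
            return mean + rng.standard_normal() / np.sqrt(prec), 0.0

        ca, cb = recenter(a_i, b_i, s_ai, s_bi, rho_i, alpha0, beta0, has_x)
        a_i -= ca
        b_i -= cb
        alpha0 += ca
        beta0 += cb
        ca, cb = recenter(a_t, b_t, s_at, s_bt, rho_t, alpha0, beta0, has_x)
        a_t -= ca
        b_t -= cb
        alpha0 += ca
        beta0 += cb

        eta = linpred()

        # ---- residual-family parameters ----
        if exg:
            # marginal-likelihood MH (e integrated out): breaks the strong
            # coupling between sigma2, lambda and the latent exponentials
            mu = eta - 1.0 / lam
            cur_ll = exgaussian_logpdf(y, mu, sig2, lam).sum()

            s_cur = np.sqrt(sig2)
            prop = s_cur * np.exp(mh["sigma"].scale * rng.standard_normal())
            prop_ll = exgaussian_logpdf(y, mu, prop**2, lam).sum()
            logr = (prop_ll - cur_ll
                    + _half_t3_logpdf(prop, sd_scale)
                    - _half_t3_logpdf(s_cur, sd_scale)
                    + np.log(prop) - np.log(s_cur))  # log-scale RW Jacobian
            if np.log(rng.random()) < logr:
                sig2 = prop**2
                cur_ll = prop_ll
                mh["sigma"].record(True)
            else:
                mh["sigma"].record(False)

            if spec.fix_lam is None:
                # compensated move: alpha0 absorbs the change in the
                # exponential mean so the Gaussian-component location
                # mu = eta - 1/lam is held fixed
                lam_prop = lam * np.exp(mh["lam"].scale * rng.standard_normal())
                d = 1.0 / lam_prop - 1.0 / lam
                prop_ll = exgaussian_logpdf(y, mu, sig2, lam_prop).sum()
                logr = (prop_ll - cur_ll
                        - invlam_rate / lam_prop + invlam_rate / lam
                        - 2.0 * np.log(lam_prop) + 2.0 * np.log(lam)
                        + np.log(lam_prop) - np.log(lam)  # RW Jacobian
                        - (alpha0 + d) ** 2 / (2 * loc_sd**2)
                        + alpha0**2 / (2 * loc_sd**2))
                if np.log(rng.random()) < logr:
                    lam = lam_prop
                    alpha0 += d
                    eta = eta + d
                    mh["lam"].record(True)
                else:
                    mh["lam"].record(False)
        else:
            nu = yg - eta
            SSE = nu @ nu

            def sig_logpost(s):
                return (-n * np.log(s) - SSE / (2 * s * s)
                        + _half_t3_logpdf(s, sd_scale) + np.log(s))

            s_cur = np.sqrt(sig2)
            prop = s_cur * np.exp(mh["sigma"].scale * rng.standard_normal())
            if np.log(rng.random()) < sig_logpost(prop) - sig_logpost(s_cur):
                sig2 = prop**2
                mh["sigma"].record(True)
            else:
                mh["sigma"].record(False)

        # ---- random-effect covariances (component-wise MH, each component
        # with its own adapted random-walk scale) ----
        def update_cov(a, b, s_a, s_b, rho, keys, with_slope):
            if not with_slope:
                key = keys[0]

                def logpost1(s):
                    return (-a.size * np.log(s) - (a @ a) / (2 * s * s)
                            + _half_t3_logpdf(s, sd_scale) + np.log(s))

                sap = s_a * np.exp(mh[key].scale * rng.standard_normal())
                if np.log(rng.random()) < logpost1(sap) - logpost1(s_a):
                    mh[key].record(True)
                    return sap, s_b, rho
                mh[key].record(False)
                return s_a, s_b, rho

            def logpost(sa_, sb_, rho_):
                return (_bivariate_normal_loglik(a, b, sa_**2, sb_**2, rho_)
                        + _half_t3_logpdf(sa_, sd_scale)
                        + _half_t3_logpdf(sb_, sd_scale)
                        + np.log(sa_) + np.log(sb_) + np.log(1 - rho_**2))

            cur = logpost(s_a, s_b, rho)
            sap = s_a * np.exp(mh[keys[0]].scale * rng.standard_normal())
            new = logpost(sap, s_b, rho)
            if np.log(rng.random()) < new - cur:
                s_a, cur = sap, new
                mh[keys[0]].record(True)
            else:
                mh[keys[0]].record(False)
            sbp = s_b * np.exp(mh[keys[1]].scale * rng.standard_normal())
            new = logpost(s_a, sbp, rho)
            if np.log(rng.random()) < new - cur:
                s_b, cur = sbp, new
                mh[keys[1]].record(True)
            else:
                mh[keys[1]].record(False)
            rhop = np.tanh(np.arctanh(rho) + mh[keys[2]].scale * rng.standard_normal())
            new = logpost(s_a, s_b, rhop)
            if np.log(rng.random()) < new - cur:
                rho = rhop
                mh[keys[2]].record(True)
            else:
                mh[keys[2]].record(False)
            return s_a, s_b, rho

        s_ai, s_bi, rho_i = update_cov(a_i, b_i, s_ai, s_bi, rho_i,
                                       ("sig_i_a", "sig_i_b", "rho_i"), has_x)
        s_at, s_bt, rho_t = update_cov(a_t, b_t, s_at, s_bt, rho_t,
                                       ("sig_t_a", "sig_t_b", "rho_t"), has_x)

        # ---- smoothing variance ----
        if has_smooth:
            Sg = gamma @ gamma

            def smooth_logpost(s):
                return (-k * np.log(s) - Sg / (2 * s * s)
                        + _half_t3_logpdf(s, sd_scale) + np.log(s))

            prop = s_smooth * np.exp(mh["smooth"].scale * rng.standard_normal())
            if np.log(rng.random()) < smooth_logpost(prop) - smooth_logpost(s_smooth):
                s_smooth = prop
                mh["smooth"].record(True)
            else:
                mh["smooth"].record(False)

        if it < spec.warmup:
            if (it + 1) % 50 == 0:
                for a in mh.values():
                    a.adapt()
            continue

        j = it - spec.warmup
        store["alpha0"][j] = alpha0
        store["beta0"][j] = beta0 if has_x else np.nan
        store["sigma2_mort"][j] = sig2
        store["lam"][j] = lam if exg else np.nan
        store["sigma2_alpha_i"][j] = s_ai**2
        store["sigma2_beta_i"][j] = s_bi**2 if has_x else np.nan
        store["rho_i"][j] = rho_i if has_x else np.nan
        store["sigma2_alpha_t"][j] = s_at**2
        store["sigma2_beta_t"][j] = s_bt**2 if has_x else np.nan
        store["rho_t"][j] = rho_t if has_x else np.nan
        store["sigma2_smooth"][j] = s_smooth**2 if has_smooth else np.nan
        store["alpha_i"][j] = a_i
        store["alpha_t"][j] = a_t
        if has_x:
            store["beta_i"][j] = b_i
            store["beta_t"][j] = b_t
        if has_smooth:
            store["gamma"][j] = gamma
        if ll_store is not None:
            if exg:
                ll = exgaussian_logpdf(y, eta - 1.0 / lam, sig2, lam)
            else:
                ll = -0.5 * (np.log(2 * np.pi * sig2) + (y - eta) ** 2 / sig2)
            ll_store[j] = ll.astype(np.float32)

    return store, ll_store


def fit_bayes(data: pd.DataFrame, spec: ModelSpec, rhat_action="raise"):
    """Fit the hierarchical drought-response model by MCMC.

    Parameters
    ----------
    data : DataFrame
        Columns ``cell_id``, ``year``, ``mort`` (fractional deviation) and,
        for the linear/smooth variants, ``cwb_z``.
    spec : ModelSpec
        Sampler and model configuration.
    rhat_action : {'raise', 'warn', 'ignore'}
        What to do when a population/family-level parameter has
        R-hat > 1.05.  Random-effect elements only ever warn.

    Returns
    -------
    ModelPosterior
        ``spec.chains * (spec.iterations - spec.warmup)`` pooled draws of
        every model parameter, with per-parameter R-hat.
    """
    need = {"cell_id", "year", "mort"}
    if spec.variant != "null":
        need.add("cwb_z")
    missing = need - set(data.columns)
    if missing:
        raise ValueError(f"data missing columns: {sorted(missing)}")
    y = data["mort"].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite response values")
    x = (data["cwb_z"].to_numpy(dtype=float) if spec.variant != "null"
         else np.zeros(len(y)))
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite CWB values")
    _, cell_idx = np.unique(data["cell_id"], return_inverse=True)
    _, year_idx = np.unique(data["year"], return_inverse=True)
    y_sd = float(np.std(y, ddof=1))

    basis = None
    B = np.zeros((len(y), 0))
    if spec.variant == "smooth":
        basis = thin_plate_basis(x, k=spec.smooth_k)
        B = basis(x)

    seeds = np.random.SeedSequence(spec.seed).spawn(spec.chains)
    results = [
        _run_chain(y, x, B, cell_idx, year_idx, spec,
                   np.random.default_rng(s), y_sd)
        for s in seeds
    ]
    draws = {
        name: np.stack([r[0][name] for r in results])
        for name in results[0][0]
    }
    loglik = (np.stack([r[1] for r in results])
              if results[0][1] is not None else None)

    rhat = _compute_rhat(draws)
    posterior = ModelPosterior(
        spec=spec, draws=draws, rhat=rhat, basis=basis,
        loglik=loglik, y_sd=y_sd, n_obs=len(y),
    )
    _check_convergence(posterior, rhat_action)
    return posterior


def _compute_rhat(draws):
    import arviz as az

    # parameters not present in a variant/family are stored as NaN; they have
    # no chains to diagnose
    live = {k: v for k, v in draws.items() if not np.all(np.isnan(v))}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.rhat(az.from_dict(posterior=live))
    out = {}
    for name, da in ds.items():
        vals = np.atleast_1d(da.values)
        if vals.size == 1:
            out[name] = float(vals.ravel()[0])
        else:
            for i, v in enumerate(vals.ravel()):
                out[f"{name}[{i}]"] = float(v)
    return pd.Series(out)


def _check_convergence(posterior, rhat_action):
    if rhat_action == "ignore":
        return
    if posterior.spec.chains < 2:
        return
    rhat = posterior.rhat.dropna()
    core = rhat[[i for i in rhat.index if "[" not in i]]
    effects = rhat[[i for i in rhat.index if "[" in i]]
    bad_core = core[core > 1.05]
    bad_eff = effects[effects > 1.05]
    if len(bad_eff):
        warnings.warn(
            f"{len(bad_eff)} random-effect elements with R-hat > 1.05 "
            f"(worst {bad_eff.max():.3f})",
            stacklevel=3,
        )
    if len(bad_core):
        msg = ("chains not converged; R-hat > 1.05 for: "
               + ", ".join(f"{k}={v:.3f}" for k, v in bad_core.items()))
        if rhat_action == "raise":
            raise ConvergenceError(msg)
        warnings.warn(msg, stacklevel=3)


def compare_models(fits: dict) -> pd.DataFrame:
    """Rank model fits by PSIS-LOO expected log predictive density.

    ``fits`` maps model names to :class:`ModelPosterior` objects fit to the
    same data with the same likelihood family.  Returns the arviz comparison
    table (``elpd_loo``, differences to the best model and their SEs), best
    model first.  A Pareto-k fraction above 0.7 exceeding 10% of points
    triggers a warning.
    """
    import arviz as az

    loos = {}
    for name, fit in fits.items():
        loo = fit.loo()
        k = np.asarray(loo.pareto_k)
        frac = float((k > 0.7).mean())
        if frac > 0.10:
            warnings.warn(
                f"model '{name}': {100 * frac:.0f}% of points with Pareto k > 0.7; "
                "LOO estimate may be unreliable",
                stacklevel=2,
            )
        loos[name] = loo
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = az.compare(
            {n: f.to_inferencedata() for n, f in fits.items()}, ic="loo"
        )
    return table
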