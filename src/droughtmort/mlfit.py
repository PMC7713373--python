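"""Gaussian maximum-likelihood fits of the crossed mixed model, for AIC
window selection.

The drought-integration window (observation month March..August x window
length 1..6 months) is chosen by fitting, for every candidate window, the
linear mixed model

    mort_it = (alpha0 + alpha_i + alpha_t) + (beta0 + beta_i + beta_t) z_it + eps
    (alpha_i, beta_i) ~ MVN(0, Sigma_i),  (alpha_t, beta_t) ~ MVN(0, Sigma_t),
    eps ~ N(0, sigma2)

by maximum likelihood and taking the smallest AIC.  The marginal likelihood
is evaluated with the Woodbury identity: the random-effect design has only
q = 2 n_cells + 2 n_years columns, so each evaluation costs one q x q
Cholesky rather than an n x n one.  Fixed effects are profiled out by GLS at
each variance-parameter value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .cwb import compute_cwb, integrate_cwb, z_transform

log = logging.getLogger(__name__)

__all__ = ["MLFit", "fit_gaussian_mixed", "fit_ml_window", "select_window"]

_N_PARAMS = 9  # alpha0, beta0 + 7 variance parameters


@dataclass
class MLFit:
    """Maximum-likelihood fit of the Gaussian crossed mixed model."""

    alpha0: float
    beta0: float
    beta0_se: float
    sigma2_alpha_i: float
    sigma2_beta_i: float
    rho_i: float
    sigma2_alpha_t: float
    sigma2_beta_t: float
    rho_t: float
    sigma2: float
    loglik: float
    aic: float
    converged: bool
    month: int | None = None
    window: int | None = None
    diagonal_fallback: bool = False


def _design(x, cell_idx, year_idx, n_cells, n_years):
    n = len(x)
    Z = np.zeros((n, 2 * n_cells + 2 * n_years))
    rows = np.arange(n)
    Z[rows, cell_idx] = 1.0
    Z[rows, n_cells + cell_idx] = x
    Z[rows, 2 * n_cells + year_idx] = 1.0
    Z[rows, 2 * n_cells + n_years + year_idx] = x
    return Z


def _ginv_logdet(theta, n_cells, n_years):
    """Inverse and log-determinant of the random-effect covariance G."""
    sa_i, sb_i, rho_i, sa_t, sb_t, rho_t = theta
    q = 2 * n_cells + 2 * n_years
    Ginv = np.zeros((q, q))

    def block(sa, sb, rho):
        det = (sa * sb) ** 2 * (1 - rho**2)
        inv = np.array(
            [[sb**2, -rho * sa * sb], [-rho * sa * sb, sa**2]]
        ) / det
        return inv, np.log(det)

    inv_i, ld_i = block(sa_i, sb_i, rho_i)
    inv_t, ld_t = block(sa_t, sb_t, rho_t)
    ic = np.arange(n_cells)
    it = 2 * n_cells + np.arange(n_years)
    Ginv[ic, ic] = inv_i[0, 0]
    Ginv[ic + n_cells, ic + n_cells] = inv_i[1, 1]
    Ginv[ic, ic + n_cells] = Ginv[ic + n_cells, ic] = inv_i[0, 1]
    Ginv[it, it] = inv_t[0, 0]
    Ginv[it + n_years, it + n_years] = inv_t[1, 1]
    Ginv[it, it + n_years] = Ginv[it + n_years, it] = inv_t[0, 1]
    logdet_g = n_cells * ld_i + n_years * ld_t
    return Ginv, logdet_g


def fit_gaussian_mixed(y, x, cell_idx, year_idx, diagonal=False):
    """ML fit of the crossed random-intercept/slope model (Gaussian errors).

    Parameters are optimized on log-SD / atanh-correlation scale with
    L-BFGS-B.  If the full fit fails (singular covariance, non-finite
    objective) the model is refit with diagonal Sigma (correlations fixed to
    zero) and flagged ``diagonal_fallback``.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    cell_idx = np.asarray(cell_idx)
    year_idx = np.asarray(year_idx)
    n = len(y)
    n_cells = cell_idx.max() + 1
    n_years = year_idx.max() + 1
    q = 2 * n_cells + 2 * n_years
    if n <= q:
        log.warning("fewer observations (%d) than random-effect columns (%d)", n, q)

    X = np.column_stack([np.ones(n), x])
    Z = _design(x, cell_idx, year_idx, n_cells, n_years)
    ZtZ = Z.T @ Z
    ZtW = Z.T @ np.column_stack([X, y])
    XtX = X.T @ X
    Xty = X.T @ y
    yty = y @ y

    def unpack(p, diag):
        if diag:
            sds = np.exp(p[:4])
            return np.array([sds[0], sds[1], 0.0, sds[2], sds[3], 0.0]), np.exp(p[4])
        sds = np.exp(p[[0, 1, 3, 4]])
        rhos = np.tanh(p[[2, 5]])
        return (
            np.array([sds[0], sds[1], rhos[0], sds[2], sds[3], rhos[1]]),
            np.exp(p[6]),
        )

    def profile(p, diag, want_fit=False):
        theta, sigma = unpack(p, diag)
        sig2 = sigma**2
        Ginv, logdet_g = _ginv_logdet(theta, n_cells, n_years)
        M = sig2 * Ginv + ZtZ
        try:
            L = np.linalg.cholesky(M)
        except np.linalg.LinAlgError:
            return (np.inf, None) if want_fit else np.inf
        logdet_m = 2.0 * np.log(np.diag(L)).sum()
        logdet_v = (n - q) * np.log(sig2) + logdet_g + logdet_m
        # A'B V^-1 style crossproducts via the Woodbury identity
        S = np.linalg.solve(L, ZtW)  # (q, 3): whitened Z'[X, y]
        XtVX = (XtX - S[:, :2].T @ S[:, :2]) / sig2
        XtVy = (Xty - S[:, :2].T @ S[:, 2]) / sig2
        ytVy = (yty - S[:, 2] @ S[:, 2]) / sig2
        try:
            beta = np.linalg.solve(XtVX, XtVy)
        except np.linalg.LinAlgError:
            return (np.inf, None) if want_fit else np.inf
        quad = ytVy - XtVy @ beta
        ll = -0.5 * (n * np.log(2 * np.pi) + logdet_v + quad)
        if not np.isfinite(ll):
            return (np.inf, None) if want_fit else np.inf
        if want_fit:
            cov_beta = np.linalg.inv(XtVX)
            return -ll, (theta, sigma, beta, cov_beta, ll)
        return -ll

    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    s0 = max(np.std(resid), 1e-3)
    if diagonal:
        p0 = np.log(np.array([s0, s0, s0, s0, s0]) * 0.5)
        bounds = [(-10, 5)] * 5
    else:
        p0 = np.array(
            [np.log(s0 / 2), np.log(s0 / 2), 0.0, np.log(s0 / 2), np.log(s0 / 2), 0.0,
             np.log(s0)]
        )
        bounds = [(-10, 5), (-10, 5), (-3, 3), (-10, 5), (-10, 5), (-3, 3), (-10, 5)]

    res = optimize.minimize(
        profile, p0, args=(diagonal,), method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500},
    )
    neg_ll, fit = profile(res.x, diagonal, want_fit=True)
    if fit is None or not np.isfinite(neg_ll):
        if diagonal:
            raise RuntimeError("Gaussian mixed-model fit failed even with diagonal Sigma")
        log.warning("singular random-effect covariance; refitting with diagonal Sigma")
        out = fit_gaussian_mixed(y, x, cell_idx, year_idx, diagonal=True)
        out.diagonal_fallback = True
        return out
    theta, sigma, beta, cov_beta, ll = fit
    n_par = _N_PARAMS - (2 if diagonal else 0)
    return MLFit(
        alpha0=beta[0],
        beta0=beta[1],
        beta0_se=float(np.sqrt(cov_beta[1, 1])),
        sigma2_alpha_i=theta[0] ** 2,
        sigma2_beta_i=theta[1] ** 2,
        rho_i=theta[2],
        sigma2_alpha_t=theta[3] ** 2,
        sigma2_beta_t=theta[4] ** 2,
        rho_t=theta[5],
        sigma2=sigma**2,
        loglik=ll,
        aic=2.0 * n_par - 2.0 * ll,
        converged=bool(res.success),
        diagonal_fallback=diagonal,
    )


def _model_frame(deviations: pd.DataFrame, cwb_z: pd.DataFrame) -> pd.DataFrame:
    frame = deviations.merge(cwb_z[["cell_id", "year", "cwb_z"]], on=["cell_id", "year"])
    if frame["mort"].isna().any() or frame["cwb_z"].isna().any():
        raise ValueError("model frame contains missing values")
    return frame


def fit_ml_window(deviations: pd.DataFrame, cwb_monthly: pd.DataFrame, month, window):
    """Fit one (observation month, integration window) candidate.

    ``deviations`` has cell_id, year, mort; ``cwb_monthly`` is the output of
    :func:`droughtmort.cwb.compute_cwb` (monthly CWB per cell).  Returns an
    :class:`MLFit` carrying the candidate's AIC.
    """
    zpanel = z_transform(integrate_cwb(cwb_monthly, month, window))
    frame = _model_frame(deviations, zpanel)
    cells, cell_idx = np.unique(frame["cell_id"], return_inverse=True)
    years, year_idx = np.unique(frame["year"], return_inverse=True)
    fit = fit_gaussian_mixed(
        frame["mort"].to_numpy(), frame["cwb_z"].to_numpy(), cell_idx, year_idx
    )
    fit.month = int(month)
    fit.window = int(window)
    return fit


def select_window(
    deviations: pd.DataFrame,
    climate: pd.DataFrame,
    months=range(3, 9),
    windows=range(1, 7),
):
    """AIC scan over all month x window candidates.

    Returns ``(best_fit, table)`` where ``table`` lists month, window, AIC and
    log-likelihood for every candidate.  Ties are broken toward the earliest
    month, then the shortest window (logged).
    """
    cwb_monthly = compute_cwb(climate)
    fits = []
    for m in months:
        for w in windows:
            fits.append(fit_ml_window(deviations, cwb_monthly, m, w))
    table = pd.DataFrame(
        {
            "month": [f.month for f in fits],
            "window": [f.window for f in fits],
            "aic": [f.aic for f in fits],
            "loglik": [f.loglik for f in fits],
            "beta0": [f.beta0 for f in fits],
        }
    ).sort_values(["aic", "month", "window"], kind="stable").reset_index(drop=True)
    best_aic = table["aic"].iloc[0]
    ties = table[np.isclose(table["aic"], best_aic)]
    if len(ties) > 1:
        log.info("AIC tie among %d candidates; earliest month/shortest window used",
                 len(ties))
    best_row = ties.sort_values(["month", "window"]).iloc[0]
    best = next(
        f for f in fits if f.month == best_row["month"] and f.window == best_row["window"]
    )
    return best, table
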