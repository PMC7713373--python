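"""Exponentially modified Gaussian (exGaussian) distribution.

The exGaussian is the convolution of a Gaussian and an exponential
distribution: ``X = G + E`` with ``G ~ N(mu, sigma2)`` and
``E ~ Exponential(rate=lam)``.  It is the right-skewed error family used for
the fractional-deviation response, where the exponential tail absorbs the few
cell-years with very large excess mortality.

Parameterization: ``mu`` is the mean of the *Gaussian component* (textbook
convention), so ``E[X] = mu + 1/lam`` and ``Var[X] = sigma2 + 1/lam**2``.
Because common implementations disagree on whether the exponential part is
given by its rate or its scale, :func:`exgaussian_logpdf` also accepts
``scale=`` as an alias for ``1/lam``.
"""

from __future__ import annotations

import numpy as np
from scipy import special

__all__ = ["exgaussian_logpdf", "exgaussian_pdf", "exgaussian_rvs", "exgaussian_mean"]


def exgaussian_logpdf(x, mu, sigma2, lam=None, *, scale=None):
    """Log-density of the exGaussian distribution, numerically stable.

    Uses the scaled complementary error function (``erfcx``) so that the
    Gaussian-dominated left flank and the exponential right tail are both
    evaluated without overflow:

    ``log f = log(lam/2) + lam*(mu - x) + lam^2 sigma2 / 2 - u^2 + log erfcx(u)``

    with ``u = (mu + lam*sigma2 - x) / (sigma * sqrt(2))``.

    Parameters
    ----------
    x : array_like
        Evaluation points.
    mu : array_like
        Mean of the Gaussian component.
    sigma2 : array_like
        Variance of the Gaussian component (> 0).
    lam : array_like, optional
        Rate of the exponential component (> 0).  Exactly one of ``lam`` and
        ``scale`` must be given; ``scale`` is the exponential mean ``1/lam``.
    """
    if (lam is None) == (scale is None):
        raise ValueError("give exactly one of `lam` (rate) or `scale` (=1/rate)")
    if lam is None:
        lam = 1.0 / np.asarray(scale, dtype=float)
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if np.any(sigma2 <= 0):
        raise ValueError("sigma2 must be positive")
    if np.any(lam <= 0):
        raise ValueError("lambda must be positive")
    sigma = np.sqrt(sigma2)
    u = (mu + lam * sigma2 - x) / (sigma * np.sqrt(2.0))
    # log erfc(u): erfcx is stable on the Gaussian-dominated flank (u >= 0)
    # but overflows for u << 0 (deep exponential tail), where erfc(u) -> 2
    # is computed directly
    u, lam, mu, sigma2, x = np.broadcast_arrays(u, lam, mu, sigma2, x)
    log_erfc = np.empty_like(u)
    pos = u >= 0
    log_erfc[pos] = -u[pos] ** 2 + np.log(special.erfcx(u[pos]))
    log_erfc[~pos] = np.log(special.erfc(u[~pos]))
    return (
        np.log(lam / 2.0)
        + lam * (mu - x)
        + 0.5 * lam**2 * sigma2
        + log_erfc
    )


def exgaussian_pdf(x, mu, sigma2, lam=None, *, scale=None):
    """Density of the exGaussian distribution (see :func:`exgaussian_logpdf`)."""
    return np.exp(exgaussian_logpdf(x, mu, sigma2, lam, scale=scale))


def exgaussian_rvs(mu, sigma2, lam, size, rng):
    """Draw exGaussian variates as Gaussian + independent Exponential(rate lam)."""
    if np.any(np.asarray(sigma2) <= 0) or np.any(np.asarray(lam) <= 0):
        raise ValueError("sigma2 and lambda must be positive")
    sigma = np.sqrt(sigma2)
    return rng.normal(mu, sigma, size=size) + rng.exponential(1.0 / lam, size=size)


def exgaussian_mean(mu, sigma2, lam):
    """Mean ``mu + 1/lam`` of the exGaussian distribution."""
    del sigma2
    return mu + 1.0 / lam
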