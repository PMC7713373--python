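"""Probability-of-excess-mortality curves and drought-threshold detection.

Posterior draws of the response model are turned into predictive draws of the
fractional mortality deviation over a grid of CWB z-scores, including both
parameter uncertainty (the posterior draw) and model uncertainty (one
random cell effect, one random year effect and one residual per draw, all
sampled from their population distributions).  The share of draws exceeding
an excess level L gives the probability curve P(mort > L | CWB); the drought
threshold is the single breakpoint of the level-0 curve, detected per
draw-bin by exhaustive two-segment least squares and summarized by its mean
and central 95% interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ProbabilityCurves",
    "BreakpointFit",
    "ThresholdResult",
    "default_grid",
    "predictive_draws",
    "probability_curves",
    "detect_breakpoint",
    "detect_threshold",
]


def default_grid(n=201, lo=-3.5, hi=2.5):
    """Default CWB evaluation grid: 201 points over [-3.5, +2.5] z-units."""
    return np.linspace(lo, hi, n)


@dataclass
class ProbabilityCurves:
    """P(excess mortality > level) over a CWB grid, with a 95% ribbon."""

    grid: np.ndarray  # (n_grid,)
    levels: tuple  # excess levels (fractional deviation)
    probability: np.ndarray  # (n_levels, n_grid) mean over all draws
    lo: np.ndarray  # (n_levels, n_grid) 2.5% over draw-bins
    hi: np.ndarray  # (n_levels, n_grid) 97.5% over draw-bins
    bin_probability: np.ndarray  # (n_levels, n_bins, n_grid)


@dataclass
class BreakpointFit:
    """Single-break two-segment OLS fit of one curve."""

    breakpoint: float
    index: int
    rss: float
    rss_no_break: float
    no_distinct_break: bool


@dataclass
class ThresholdResult:
    """Per-bin breakpoints of the probability curve with central interval."""

    breakpoints: np.ndarray
    estimate: float
    ci_low: float
    ci_high: float
    level: float
    n_flat: int  # bins flagged as having no distinct break


def predictive_draws(posterior, grid, rng):
    """Predictive fractional-deviation draws, shape (n_draws, n_grid).

    One cell-effect pair, one year-effect pair and one residual are sampled
    per posterior draw from their population distributions, so each row is a
    plausible realized cell-year response curve.
    """
    grid = np.asarray(grid, dtype=float)
    nd = posterior.n_draws

    def get(name, fallback=0.0):
        if name in posterior.draws:
            v = posterior.stacked(name)
            if not np.all(np.isnan(v)):
                return v
        return np.full(nd, fallback)

    alpha0 = get("alpha0")
    beta0 = get("beta0")
    s_ai = np.sqrt(get("sigma2_alpha_i"))
    s_bi = np.sqrt(get("sigma2_beta_i"))
    rho_i = get("rho_i")
    s_at = np.sqrt(get("sigma2_alpha_t"))
    s_bt = np.sqrt(get("sigma2_beta_t"))
    rho_t = get("rho_t")
    sig = np.sqrt(get("sigma2_mort"))
    lam = posterior.stacked("lam") if "lam" in posterior.draws else np.full(nd, np.nan)

    def bvn(sa, sb, rho):
        z1 = rng.standard_normal(nd)
        z2 = rng.standard_normal(nd)
        return sa * z1, sb * (rho * z1 + np.sqrt(1.0 - rho**2) * z2)

    ai, bi = bvn(s_ai, s_bi, rho_i)
    at, bt = bvn(s_at, s_bt, rho_t)
    eps = sig * rng.standard_normal(nd)
    exg = np.isfinite(lam)
    if exg.any():  # centered exponential component of the exGaussian residual
        eps[exg] += rng.exponential(1.0 / lam[exg]) - 1.0 / lam[exg]

    intercept = alpha0 + ai + at
    slope = beta0 + bi + bt
    mort = intercept[:, None] + slope[:, None] * grid[None, :] + eps[:, None]
    if "gamma" in posterior.draws and posterior.basis is not None:
        Bg = posterior.basis(grid)  # (n_grid, k)
        mort = mort + posterior.stacked("gamma") @ Bg.T
    return mort


def probability_curves(posterior, grid=None, levels=(0.0, 0.25, 0.5, 1.0),
                       n_bins=100, seed=0):
    """Probability of exceeding each excess level over the CWB grid.

    The ribbon follows the draw-binning construction: the pooled draws are
    split into ``n_bins`` consecutive bins (100 bins of 80 draws for the
    default 8,000), the probability is recomputed per bin, and the 2.5/97.5
    percentiles over bins bound the ribbon.  If there are fewer draws than
    bins the bin count is reduced with a warning.
    """
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    mort = predictive_draws(posterior, grid, rng)
    nd = mort.shape[0]
    if nd < n_bins:
        warnings.warn(f"only {nd} draws; reducing ribbon bins from {n_bins} to {nd}",
                      stacklevel=2)
        n_bins = nd
    usable = (nd // n_bins) * n_bins
    binned = mort[:usable].reshape(n_bins, usable // n_bins, len(grid))

    levels = tuple(levels)
    probability = np.empty((len(levels), len(grid)))
    bin_prob = np.empty((len(levels), n_bins, len(grid)))
    for j, lev in enumerate(levels):
        probability[j] = (mort > lev).mean(axis=0)
        bin_prob[j] = (binned > lev).mean(axis=1)
    lo = np.percentile(bin_prob, 2.5, axis=1)
    hi = np.percentile(bin_prob, 97.5, axis=1)
    return ProbabilityCurves(grid=grid, levels=levels, probability=probability,
                             lo=lo, hi=hi, bin_probability=bin_prob)


def detect_breakpoint(x, y, min_segment_frac=0.15):
    """Best single breakpoint of ``y(x)`` by exhaustive two-segment OLS.

    Every admissible split (each segment at least ``min_segment_frac`` of the
    points) is scored by the summed residual sum of squares of two
    independently fitted lines; the split minimizing the RSS wins.  Exactly
    linear or flat input produces no RSS improvement: the smallest candidate
    index is returned and the fit is flagged ``no_distinct_break``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 grid points for breakpoint detection")
    min_seg = max(int(np.ceil(min_segment_frac * n)), 2)

    # prefix/suffix OLS RSS from cumulative sums
    cx, cy = np.cumsum(x), np.cumsum(y)
    cxx, cyy, cxy = np.cumsum(x * x), np.cumsum(y * y), np.cumsum(x * y)

    def seg_rss(sx, sy, sxx, syy, sxy, m):
        # RSS of an OLS line through m points with the given sums
        vx = sxx - sx * sx / m
        vy = syy - sy * sy / m
        vxy = sxy - sx * sy / m
        with np.errstate(divide="ignore", invalid="ignore"):
            out = vy - np.where(vx > 0, vxy * vxy / np.where(vx > 0, vx, 1.0), 0.0)
        return np.maximum(out, 0.0)

    # candidate c = size of the left segment
    cand = np.arange(min_seg, n - min_seg + 1)
    lm = cand.astype(float)
    left = seg_rss(cx[cand - 1], cy[cand - 1], cxx[cand - 1], cyy[cand - 1],
                   cxy[cand - 1], lm)
    rm = n - lm
    right = seg_rss(cx[-1] - cx[cand - 1], cy[-1] - cy[cand - 1],
                    cxx[-1] - cxx[cand - 1], cyy[-1] - cyy[cand - 1],
                    cxy[-1] - cxy[cand - 1], rm)
    total = left + right
    best = int(np.argmin(total))  # exact ties resolve to the smallest index
    rss0 = float(seg_rss(cx[-1], cy[-1], cxx[-1], cyy[-1], cxy[-1], float(n)))
    improvement = rss0 - total[best]
    flat = bool(improvement <= max(1e-12, 1e-9 * max(rss0, 1e-30)))
    if flat:
        best = 0  # no distinct break: rounding noise must not pick a winner
    idx = cand[best] - 1  # last point of the left segment
    return BreakpointFit(
        breakpoint=float(x[idx]), index=int(idx), rss=float(total[best]),
        rss_no_break=rss0, no_distinct_break=flat,
    )


def detect_threshold(posterior=None, curves=None, grid=None, level=0.0,
                     n_bins=100, seed=0, min_segment_frac=0.15):
    """Drought threshold: per-bin breakpoint of the P(excess > level) curve.

    Either a fitted posterior or precomputed :class:`ProbabilityCurves` can
    be supplied.  Each draw-bin's probability curve gets its own breakpoint;
    the threshold estimate is their mean with the central 95% interval.
    """
    if curves is None:
        if posterior is None:
            raise ValueError("need a posterior or precomputed curves")
        curves = probability_curves(posterior, grid=grid, n_bins=n_bins, seed=seed)
    try:
        j = list(curves.levels).index(level)
    except ValueError:
        raise ValueError(f"level {level} not among computed levels {curves.levels}")
    bps = []
    n_flat = 0
    for curve in curves.bin_probability[j]:
        fit = detect_breakpoint(curves.grid, curve, min_segment_frac)
        bps.append(fit.breakpoint)
        n_flat += fit.no_distinct_break
    bps = np.asarray(bps)
    return ThresholdResult(
        breakpoints=bps,
        estimate=float(bps.mean()),
        ci_low=float(np.percentile(bps, 2.5)),
        ci_high=float(np.percentile(bps, 97.5)),
        level=level,
        n_flat=int(n_flat),
    ), curves
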