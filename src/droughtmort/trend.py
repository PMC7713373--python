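"""Long-term canopy-mortality trends and the excess-mortality statistic.

Gridded annual canopy-mortality counts (30 m pixels aggregated to 0.5 degree
cells) are screened against a non-forest-ecoregion mask, each retained cell's
long-term mortality trend is fit as a binomial logistic regression of the
annual mortality proportion on calendar year, and the excess-mortality
statistic is the fractional deviation of the observed rate from the fitted
trend:

    mort_it = (observed_rate - fitted_rate) / fitted_rate

so 0 means mortality on trend, +1.0 a doubling of the annual mortality area,
and -1.0 no mortality at all.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit

PIXEL_AREA_HA = 0.09  # one 30 m x 30 m Landsat pixel

log = logging.getLogger(__name__)

__all__ = [
    "PIXEL_AREA_HA",
    "TrendFit",
    "exclude_nonforest_cells",
    "fit_trend",
    "fit_all_trends",
    "fractional_deviation",
    "deviation_panel",
]


@dataclass
class TrendFit:
    """Binomial-logit trend of one cell's annual mortality rate."""

    cell_id: object
    intercept: float  # logit scale, at the series midpoint year
    slope: float  # logit scale, per year
    years: np.ndarray
    fitted_rate: np.ndarray
    converged: bool

    def rate_at(self, years):
        """Fitted mortality rate for the given calendar years."""
        years = np.asarray(years, dtype=float)
        if not self.converged:
            return np.full(years.shape, self.fitted_rate[0])
        mid = self.years.mean()
        return expit(self.intercept + self.slope * (years - mid))


def exclude_nonforest_cells(panel: pd.DataFrame, mask: pd.Series) -> pd.DataFrame:
    """Drop cells flagged as majority non-forest ecoregion.

    ``mask`` is a boolean Series indexed by cell_id (True = exclude).  Every
    cell in the panel must be covered by the mask; missing cells are an error.
    """
    cells = pd.Index(panel["cell_id"].unique())
    missing = cells.difference(mask.index)
    if len(missing):
        raise ValueError(f"mask does not cover cells: {list(missing)[:10]}")
    flagged = set(mask.index[mask.astype(bool)])
    keep = ~panel["cell_id"].isin(flagged)
    n_removed = cells.isin(flagged).sum()
    n_kept = len(cells) - n_removed
    log.info(
        "excluded %d of %d cells (%.0f%%); %d retained",
        n_removed, len(cells), 100.0 * n_removed / max(len(cells), 1), n_kept,
    )
    if n_kept == 0:
        warnings.warn("all cells flagged non-forest; empty panel returned", stacklevel=2)
    return panel.loc[keep].reset_index(drop=True)


def fit_trend(cell_series: pd.DataFrame) -> TrendFit:
    """Fit one cell's long-term mortality trend.

    ``cell_series`` has columns year, forest_pixels, mortality_pixels for a
    single cell.  The trend is a binomial GLM of the mortality proportion on
    calendar year (centered at the series midpoint for conditioning).  Cells
    with all-zero mortality or a non-converged/degenerate fit fall back to a
    constant smoothed pooled rate (total mortality + 0.5) / (total forest + 1)
    and are flagged ``converged=False``.
    """
    df = cell_series.sort_values("year")
    years = df["year"].to_numpy(dtype=float)
    forest = df["forest_pixels"].to_numpy(dtype=float)
    dead = df["mortality_pixels"].to_numpy(dtype=float)
    if (forest > 0).sum() < 3:
        raise ValueError("need at least 3 years with forest pixels")
    if np.any(dead > forest):
        raise ValueError("mortality pixels exceed forest pixels")
    cell_id = df["cell_id"].iloc[0] if "cell_id" in df else None

    fallback_rate = (dead.sum() + 0.5) / (forest.sum() + 1.0)
    mid = years.mean()
    ok = forest > 0
    if dead[ok].sum() > 0 and dead[ok].sum() < forest[ok].sum():
        X = sm.add_constant(years[ok] - mid)
        endog = np.column_stack([dead[ok], forest[ok] - dead[ok]])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
            if res.converged and np.all(np.isfinite(res.params)) and abs(res.params[1]) < 5:
                rate = res.predict(sm.add_constant(years - mid, has_constant="add"))
                return TrendFit(cell_id, res.params[0], res.params[1], years,
                                np.clip(rate, 1e-12, 1 - 1e-12), True)
        except (np.linalg.LinAlgError, ValueError):
            pass
    return TrendFit(cell_id, float(logit(np.clip(fallback_rate, 1e-12, 1 - 1e-12))),
                    0.0, years, np.full(len(years), fallback_rate), False)


def fit_all_trends(panel: pd.DataFrame) -> dict:
    """Fit the trend of every cell in the panel -> {cell_id: TrendFit}."""
    return {cid: fit_trend(grp) for cid, grp in panel.groupby("cell_id", sort=False)}


def fractional_deviation(observed_rate, fitted_rate):
    """Excess-mortality statistic ``(observed - fitted) / fitted``.

    +1.0 is a doubling of the annual canopy-mortality area relative to the
    long-term trend; -1.0 is a complete mortality deficit.  ``fitted_rate``
    must be strictly positive (non-converged cells use the fallback trend).
    """
    observed_rate = np.asarray(observed_rate, dtype=float)
    fitted_rate = np.asarray(fitted_rate, dtype=float)
    if np.any(fitted_rate <= 0):
        raise ValueError("fitted_rate must be > 0; apply the fallback trend first")
    return (observed_rate - fitted_rate) / fitted_rate


def deviation_panel(panel: pd.DataFrame, fits: dict | None = None) -> pd.DataFrame:
    """Per cell-year fractional deviation table.

    Returns columns cell_id, year, forest_pixels, mortality_pixels,
    observed_rate, fitted_rate, mort (the fractional deviation) and the
    per-cell convergence flag.  Years with zero forest pixels are dropped.
    """
    if fits is None:
        fits = fit_all_trends(panel)
    df = panel.loc[panel["forest_pixels"] > 0].copy()
    df["observed_rate"] = df["mortality_pixels"] / df["forest_pixels"]
    fitted = np.empty(len(df))
    conv = np.empty(len(df), dtype=bool)
    for cid, idx in df.groupby("cell_id", sort=False).indices.items():
        fit = fits[cid]
        fitted[idx] = fit.rate_at(df["year"].to_numpy()[idx])
        conv[idx] = fit.converged
    df["fitted_rate"] = fitted
    df["trend_converged"] = conv
    df["mort"] = fractional_deviation(df["observed_rate"], df["fitted_rate"])
    return df.reset_index(drop=True)
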