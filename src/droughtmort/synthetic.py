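"""Synthetic gridded mortality and climate panels with recorded ground truth.

The study design this package targets is inferential: satellite-derived
canopy-mortality counts per 0.5 degree cell and year, a per-cell logistic
mortality trend, and a hierarchical response of the fractional trend
deviation to the climatic water balance.  This module inverts that structure
into a generator so every downstream stage can be exercised against known
truth:

* monthly climate = per-cell seasonal cycle + AR(1) monthly anomalies,
* fractional deviation ``mort_it`` = (alpha0 + alpha_i + alpha_t)
  + (beta0 + beta_i + beta_t) * z_it [+ hinge term] + eps, with crossed
  cell/year random effects drawn from zero-centered bivariate normals and
  mean-zero exGaussian noise,
* expected mortality rate = trend_rate * (1 + mort_it), floored at 0 and
  capped at 1 (the exact inverse of the fractional-deviation statistic),
* observed counts ~ Binomial(pixels_per_cell, rate).

Default parameter values are the posterior means of the full-model fit the
package is designed to recover (slope -1.88, spatial intercept/slope
variances 0.18/0.03, temporal 0.08/0.04, correlations 0.03/-0.08, residual
variance 0.13, exponential rate 0.53), with a 150-cell x 30-year panel and
10,000 forest pixels (900 ha) per cell.

A single integer seed is split into named substreams (climate, effects,
noise, binomial) via ``numpy.random.SeedSequence.spawn`` so each stage can be
regenerated independently and identically.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .cwb import cwb_z_panel

__all__ = [
    "ClimateParams",
    "TruthConfig",
    "SyntheticDataset",
    "generate_climate",
    "generate_mortality",
    "generate_dataset",
    "standard_normal_cwb",
]

_SUBSTREAMS = ("climate", "effects", "noise", "binomial")


@dataclass(frozen=True)
class ClimateParams:
    """Monthly climate generator settings (temperature degC, precip mm/month)."""

    temp_mean: float = 8.0
    temp_lat_gradient: float = -0.4  # degC per degree latitude away from 52N
    temp_seasonal_amplitude: float = 9.0
    temp_noise_sd: float = 1.5
    precip_mean: float = 70.0
    precip_seasonal_amplitude: float = 15.0
    precip_noise_sd: float = 25.0
    autocorr: float = 0.5  # month-to-month AR(1) of the anomalies
    cell_temp_sd: float = 2.0  # between-cell spread of the annual mean
    cell_precip_sd: float = 12.0
    lat_range: tuple = (40.0, 65.0)

    def validate(self):
        if self.temp_noise_sd < 0 or self.precip_noise_sd < 0:
            raise ValueError("climate noise SDs must be non-negative")
        if not -1 < self.autocorr < 1:
            raise ValueError("climate autocorrelation must be in (-1, 1)")


@dataclass(frozen=True)
class TruthConfig:
    """Ground-truth parameters of the synthetic study.

    The response parameters mirror the hierarchical model the pipeline fits:
    population intercept/slope (``alpha0``, ``beta0``), spatial and temporal
    random-effect covariances (variances + correlation), mean-zero exGaussian
    noise (Gaussian variance ``sigma2_mort``, exponential rate ``lam``), and
    an optional hinge-shaped response with a kink at ``hinge_location``
    (z-units) and slope ``hinge_slope_below`` (<= 0) left of it.
    """

    n_cells: int = 150
    n_years: int = 30
    start_year: int = 1987
    pixels_per_cell: int = 10_000  # 30 m pixels; 0.09 ha each -> 900 ha forest
    trend_intercept_mean: float = -5.0  # logit scale at the midpoint year
    trend_intercept_sd: float = 0.5
    trend_slope_mean: float = 0.02  # mortality rates drifting upward
    trend_slope_sd: float = 0.01
    alpha0: float = 0.01
    beta0: float = -1.88
    sigma2_alpha_i: float = 0.18
    sigma2_beta_i: float = 0.03
    rho_i: float = 0.03
    sigma2_alpha_t: float = 0.08
    sigma2_beta_t: float = 0.04
    rho_t: float = -0.08
    sigma2_mort: float = 0.13
    lam: float = 0.53
    response_shape: str = "linear"  # or "hinge"
    hinge_location: float = -1.6
    hinge_slope_below: float = -1.5
    driver_month: int = 7  # CWB window that actually drives mortality
    driver_window: int = 5  # (July, 5 months) = March-July
    climate_params: ClimateParams = field(default_factory=ClimateParams)
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1 or self.n_years < 3:
            raise ValueError("need n_cells >= 1 and n_years >= 3")
        if self.pixels_per_cell < 1:
            raise ValueError("pixels_per_cell must be positive")
        for name in ("sigma2_alpha_i", "sigma2_beta_i", "sigma2_alpha_t",
                     "sigma2_beta_t", "sigma2_mort"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        for name in ("rho_i", "rho_t"):
            if not -1 < getattr(self, name) < 1:
                raise ValueError(f"{name} must be in (-1, 1)")
        if self.response_shape not in ("linear", "hinge"):
            raise ValueError("response_shape must be 'linear' or 'hinge'")
        if self.response_shape == "hinge" and self.hinge_slope_below > 0:
            raise ValueError("hinge_slope_below must be <= 0")
        self.climate_params.validate()

    def substreams(self):
        """Named independent random generators derived from the seed."""
        children = np.random.SeedSequence(self.seed).spawn(len(_SUBSTREAMS))
        return {n: np.random.default_rng(s) for n, s in zip(_SUBSTREAMS, children)}

    def years(self):
        return np.arange(self.start_year, self.start_year + self.n_years)

    def to_json(self, path):
        d = asdict(self)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, default=str)


@dataclass
class SyntheticDataset:
    """Generated panels plus every realized random draw (for recovery tests)."""

    mortality_panel: pd.DataFrame  # cell_id, year, forest_pixels, mortality_pixels, lat, lon
    cwb_z: pd.DataFrame  # cell_id, year, cwb_z
    truth: dict  # config + realized effects / noise / target deviations
    climate_panel: pd.DataFrame | None = None

    def model_frame(self, source="panel", fits=None):
        """Long frame (cell_id, year, mort, cwb_z) for the response model.

        ``source='truth'`` uses the generator's target fractional deviations
        (the response-model equations exactly, no observation layer);
        ``source='panel'`` runs the observational route: counts -> per-cell
        trend fit -> fractional deviation.
        """
        if source == "truth":
            df = self.truth["deviations"].copy()
        elif source == "panel":
            from .trend import deviation_panel

            df = deviation_panel(self.mortality_panel, fits=fits)[
                ["cell_id", "year", "mort"]
            ]
        else:
            raise ValueError("source must be 'truth' or 'panel'")
        return df.merge(self.cwb_z[["cell_id", "year", "cwb_z"]], on=["cell_id", "year"])


def _seasonal(month, amplitude, peak_month=7):
    return amplitude * np.cos(2 * np.pi * (month - peak_month) / 12.0)


def _ar1(rng, n_series, n_steps, phi, sd):
    """Stationary AR(1) anomalies with marginal SD ``sd``; shape (n_series, n_steps)."""
    x = np.empty((n_series, n_steps))
    x[:, 0] = rng.normal(0.0, sd, n_series)
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    eps = rng.normal(0.0, innov_sd, (n_series, n_steps - 1))
    for t in range(1, n_steps):
        x[:, t] = phi * x[:, t - 1] + eps[:, t - 1]
    return x


def generate_climate(config: TruthConfig, rng=None) -> pd.DataFrame:
    """Monthly temperature and precipitation per cell.

    Covers the full calendar year before ``start_year`` (spin-up for the
    antecedent months of up-to-6-month windows) through the last analysis
    year.  Precipitation is floored at zero after adding anomalies.
    """
    cp = config.climate_params
    cp.validate()
    if rng is None:
        rng = config.substreams()["climate"]
    n = config.n_cells
    lats = np.linspace(cp.lat_range[0], cp.lat_range[1], n)
    lons = np.linspace(-10.0, 30.0, n)
    years = np.arange(config.start_year - 1, config.start_year + config.n_years)
    months = np.arange(1, 13)
    n_steps = len(years) * 12

    cell_temp = (
        cp.temp_mean
        + cp.temp_lat_gradient * (lats - 52.0)
        + rng.normal(0.0, cp.cell_temp_sd, n)
    )
    cell_precip = cp.precip_mean + rng.normal(0.0, cp.cell_precip_sd, n)

    t_anom = _ar1(rng, n, n_steps, cp.autocorr, cp.temp_noise_sd)
    p_anom = _ar1(rng, n, n_steps, cp.autocorr, cp.precip_noise_sd)

    month_grid = np.tile(months, len(years))
    temp = (
        cell_temp[:, None]
        + _seasonal(month_grid, cp.temp_seasonal_amplitude)[None, :]
        + t_anom
    )
    precip = np.maximum(
        cell_precip[:, None]
        + _seasonal(month_grid, cp.precip_seasonal_amplitude)[None, :]
        + p_anom,
        0.0,
    )

    idx = pd.MultiIndex.from_product(
        [np.arange(n), years, months], names=["cell", "year", "month"]
    )
    out = pd.DataFrame(index=idx).reset_index()
    out["cell_id"] = out["cell"]
    out["lat"] = lats[out["cell"]]
    out["lon"] = lons[out["cell"]]
    out["temperature"] = temp.ravel()
    out["precipitation"] = precip.ravel()
    return out.drop(columns="cell")


def standard_normal_cwb(config: TruthConfig, rng=None) -> pd.DataFrame:
    """IID standard-normal CWB z-scores for all cell-years (no climate route)."""
    if rng is None:
        rng = config.substreams()["climate"]
    cells = np.arange(config.n_cells)
    years = config.years()
    idx = pd.MultiIndex.from_product([cells, years], names=["cell_id", "year"])
    out = pd.DataFrame(index=idx).reset_index()
    out["cwb_z"] = rng.standard_normal(len(out))
    return out


def response_curve(config: TruthConfig, z):
    """Population-level response at CWB z-scores ``z`` (no noise, no effects)."""
    z = np.asarray(z, dtype=float)
    mean = config.alpha0 + config.beta0 * z
    if config.response_shape == "hinge":
        mean = mean + config.hinge_slope_below * np.minimum(z - config.hinge_location, 0.0)
    return mean


def generate_mortality(config: TruthConfig, cwb_z: pd.DataFrame) -> SyntheticDataset:
    """Draw the mortality panel given per cell-year CWB z-scores.

    Every realized random quantity (trend parameters, crossed random effects,
    exGaussian noise, target deviations) is stored in ``truth`` so recovery
    can be checked stage by stage.
    """
    if config.pixels_per_cell < 1:
        raise ValueError("pixels_per_cell must be positive")
    streams = config.substreams()
    eff, noise_rng, bin_rng = streams["effects"], streams["noise"], streams["binomial"]

    cells = np.sort(cwb_z["cell_id"].unique())
    years = config.years()
    need = pd.MultiIndex.from_product([cells, years])
    have = pd.MultiIndex.from_frame(cwb_z[["cell_id", "year"]])
    if not need.isin(have).all():
        raise ValueError("cwb_z must cover all cells x years")

    df = cwb_z.set_index(["cell_id", "year"]).loc[need].reset_index()
    df.columns = ["cell_id", "year", *df.columns[2:]]
    z = df["cwb_z"].to_numpy()
    cell_idx = df["cell_id"].map({c: k for k, c in enumerate(cells)}).to_numpy()
    year_idx = df["year"].map({y: k for k, y in enumerate(years)}).to_numpy()

    a_i = eff.normal(config.trend_intercept_mean, config.trend_intercept_sd, len(cells))
    b_i = eff.normal(config.trend_slope_mean, config.trend_slope_sd, len(cells))

    def mvn2(s2a, s2b, rho, size):
        sa, sb = np.sqrt(s2a), np.sqrt(s2b)
        cov = np.array([[s2a, rho * sa * sb], [rho * sa * sb, s2b]])
        return eff.multivariate_normal(np.zeros(2), cov, size=size)

    re_cell = mvn2(config.sigma2_alpha_i, config.sigma2_beta_i, config.rho_i, len(cells))
    re_year = mvn2(config.sigma2_alpha_t, config.sigma2_beta_t, config.rho_t, len(years))

    # mean-zero exGaussian noise: Gaussian + centered Exponential
    gauss = noise_rng.normal(0.0, np.sqrt(config.sigma2_mort), len(df))
    expo = noise_rng.exponential(1.0 / config.lam, len(df))
    eps = gauss + expo - 1.0 / config.lam

    linpred = (
        config.alpha0
        + re_cell[cell_idx, 0]
        + re_year[year_idx, 0]
        + (config.beta0 + re_cell[cell_idx, 1] + re_year[year_idx, 1]) * z
    )
    if config.response_shape == "hinge":
        linpred = linpred + config.hinge_slope_below * np.minimum(
            z - config.hinge_location, 0.0
        )
    mort = linpred + eps

    mid = years.mean()
    trend_rate = expit(a_i[cell_idx] + b_i[cell_idx] * (df["year"].to_numpy() - mid))
    rate = np.clip(trend_rate * (1.0 + mort), 0.0, 1.0)
    counts = bin_rng.binomial(config.pixels_per_cell, rate)

    panel = pd.DataFrame(
        {
            "cell_id": df["cell_id"],
            "year": df["year"],
            "forest_pixels": config.pixels_per_cell,
            "mortality_pixels": counts,
        }
    )
    truth = {
        "config": config,
        "trend_intercept": a_i,
        "trend_slope": b_i,
        "alpha_i": re_cell[:, 0],
        "beta_i": re_cell[:, 1],
        "alpha_t": re_year[:, 0],
        "beta_t": re_year[:, 1],
        "eps": eps,
        "trend_rate": trend_rate,
        "rate": rate,
        "deviations": pd.DataFrame(
            {"cell_id": df["cell_id"], "year": df["year"], "mort": mort}
        ),
    }
    return SyntheticDataset(
        mortality_panel=panel, cwb_z=df[["cell_id", "year", "cwb_z"]], truth=truth
    )


def generate_dataset(config: TruthConfig) -> SyntheticDataset:
    """Full route: climate -> windowed z-scored CWB -> mortality panel.

    Mortality is driven by the (driver_month, driver_window) CWB combination;
    the climate panel is attached so the pipeline's own CWB stage can re-derive
    the index (and the window-selection stage can rediscover the driver).
    """
    climate = generate_climate(config)
    zpanel = cwb_z_panel(climate, config.driver_month, config.driver_window)
    zpanel = zpanel[zpanel["year"].isin(config.years())]
    ds = generate_mortality(config, zpanel[["cell_id", "year", "cwb_z"]])
    ds.climate_panel = climate
    lat = climate.groupby("cell_id")[["lat", "lon"]].first()
    ds.mortality_panel = ds.mortality_panel.merge(lat, on="cell_id")
    return ds
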