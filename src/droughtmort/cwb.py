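"""Climatic water balance: Thornthwaite PET, windowed integration, z-scores.

The drought index is the climatic water balance (CWB), the difference between
the monthly precipitation sum and the monthly potential evapotranspiration
(PET) estimated from mean monthly temperature with the Thornthwaite equation.
To capture droughts of different durations the monthly CWB is averaged over
windows of one to six months ending in each month from March to August
("left-centered" windows, i.e. the w months up to and including the
observation month), and each windowed series is z-scored per grid cell over
the full record so the index expresses the local anomaly in units of local
interannual standard deviations.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "day_length_hours",
    "thornthwaite_pet",
    "compute_cwb",
    "integrate_cwb",
    "z_transform",
    "cwb_z_panel",
]

_DAYS_PER_MONTH = np.array([31, 28.25, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
# mid-month day-of-year used for the solar declination
_MID_MONTH_DOY = np.array([15, 46, 74, 105, 135, 166, 196, 227, 258, 288, 319, 349])

MONTH_NUMBERS = {
    "jan": 1, "feb": 2, "mar": 3, "apr": 4, "may": 5, "jun": 6,
    "jul": 7, "aug": 8, "sep": 9, "oct": 10, "nov": 11, "dec": 12,
}


def day_length_hours(latitude, doy=_MID_MONTH_DOY):
    """Mean day length (hours) at ``latitude`` for the given days of year.

    Standard solar-declination geometry; the sunset hour angle is clamped at
    polar latitudes (polar day -> 24 h, polar night -> 0 h).
    """
    lat = np.deg2rad(np.asarray(latitude, dtype=float))
    decl = 0.409 * np.sin(2 * np.pi * np.asarray(doy) / 365.25 - 1.39)
    cos_ws = -np.tan(lat)[..., None] * np.tan(decl)
    clamped = np.clip(cos_ws, -1.0, 1.0)
    ws = np.arccos(clamped)
    return np.squeeze(24.0 / np.pi * ws)


def thornthwaite_pet(monthly_temperature, latitude):
    """Thornthwaite potential evapotranspiration, mm per month.

    Parameters
    ----------
    monthly_temperature : array_like, shape (..., 12) or (n_years, 12)
        Mean monthly temperature in deg C, January..December per row.
    latitude : float
        Latitude of the cell center in degrees.

    Returns
    -------
    ndarray
        PET in mm/month, same shape as the input.

    Notes
    -----
    Per year: heat index ``I = sum (T/5)^1.514`` over months with T > 0;
    exponent ``a = 6.75e-7 I^3 - 7.71e-5 I^2 + 1.792e-2 I + 0.49239``;
    unadjusted ``PET = 16 (10 T / I)^a`` for T > 0, corrected by
    (day length / 12) * (days in month / 30).  PET is 0 for T <= 0, and all
    months are 0 when every month is at or below freezing (I = 0).
    """
    t = np.asarray(monthly_temperature, dtype=float)
    if t.shape[-1] != 12:
        raise ValueError("monthly_temperature must have 12 months per year")
    if abs(latitude) > 66.5:
        warnings.warn(
            f"latitude {latitude:.1f} is poleward of the polar circle; "
            "day-length correction clamped",
            stacklevel=2,
        )
    t2d = np.atleast_2d(t)
    warm = t2d > 0.0
    heat = np.where(warm, (np.maximum(t2d, 0.0) / 5.0) ** 1.514, 0.0).sum(axis=1)
    a = 6.75e-7 * heat**3 - 7.71e-5 * heat**2 + 1.792e-2 * heat + 0.49239
    pet = np.zeros_like(t2d)
    ok = heat > 0
    if np.any(ok):
        base = 16.0 * (10.0 * np.maximum(t2d[ok], 0.0) / heat[ok, None]) ** a[ok, None]
        corr = (day_length_hours(latitude) / 12.0) * (_DAYS_PER_MONTH / 30.0)
        pet[ok] = np.where(warm[ok], base * corr, 0.0)
    return pet.reshape(t.shape)


def compute_cwb(climate: pd.DataFrame) -> pd.DataFrame:
    """Monthly climatic water balance per cell from a long climate table.

    ``climate`` needs columns cell_id, lat, year, month, temperature,
    precipitation.  Returns the same table with ``pet`` and
    ``cwb = precipitation - pet`` added.
    """
    required = {"cell_id", "lat", "year", "month", "temperature", "precipitation"}
    missing = required - set(climate.columns)
    if missing:
        raise ValueError(f"climate table missing columns: {sorted(missing)}")
    out = climate.sort_values(["cell_id", "year", "month"]).copy()
    pet = np.empty(len(out))
    pos = 0
    for (_, lat), grp in out.groupby(["cell_id", "lat"], sort=False):
        tmat = grp["temperature"].to_numpy().reshape(-1, 12)
        pet[pos : pos + tmat.size] = thornthwaite_pet(tmat, lat).ravel()
        pos += tmat.size
    out["pet"] = pet
    out["cwb"] = out["precipitation"] - out["pet"]
    return out


def integrate_cwb(cwb: pd.DataFrame, month, window, years=None) -> pd.DataFrame:
    """Windowed CWB: mean over the ``window`` months ending at ``month``.

    ``month`` may be 1-12 or a name ("mar".."aug"); ``window`` in 1..6.  The
    window reaches into the previous calendar year when ``window > month``
    (e.g. February, w=4 averages Nov-Feb), so the monthly series must include
    those antecedent months.

    ``years`` selects the analysis years.  By default all years whose full
    window is present are used (a leading spin-up year that only supplies
    antecedent months is then excluded automatically); if ``years`` is given
    explicitly, a missing antecedent month is an error naming the gap.
    Returns one row per cell and analysis year with column ``cwb_window``.
    """
    if isinstance(month, str):
        month = MONTH_NUMBERS[month.lower()[:3]]
    if not 1 <= window <= 12:
        raise ValueError("window must be in 1..12")
    months = [(month - k - 1) % 12 + 1 for k in range(window)]  # m, m-1, ...
    year_offsets = [-(1 if month - k <= 0 else 0) for k in range(window)]

    tab = cwb.set_index(["cell_id", "year", "month"])["cwb"]
    present = set(zip(cwb["year"], cwb["month"]))
    all_years = sorted({y for y, m in present if m == month})
    if years is None:
        years = [
            yr
            for yr in all_years
            if all((yr + off, mo) in present for mo, off in zip(months, year_offsets))
        ]
        if not years:
            raise ValueError("no year has the complete integration window")
    else:
        years = list(years)

    pieces = []
    for yr in years:
        acc = None
        for mo, off in zip(months, year_offsets):
            try:
                vals = tab.xs((yr + off, mo), level=("year", "month"))
            except KeyError:
                msg = (
                    f"missing antecedent month {mo} of year {yr + off} "
                    f"for window ({month}, {window})"
                )
                raise ValueError(msg) from None
            acc = vals if acc is None else acc.add(vals, fill_value=np.nan)
        pieces.append(
            pd.DataFrame(
                {"cell_id": acc.index, "year": yr, "cwb_window": acc.to_numpy() / window}
            )
        )
    return pd.concat(pieces, ignore_index=True)


def z_transform(windowed: pd.DataFrame, value_col="cwb_window") -> pd.DataFrame:
    """Per-cell z-score of the windowed series over all years (ddof=1)."""
    out = windowed.copy()
    grp = out.groupby("cell_id")[value_col]
    mean = grp.transform("mean")
    sd = grp.transform("std")  # pandas default ddof=1
    bad = out.loc[sd <= 0, "cell_id"].unique()
    if len(bad):
        raise ValueError(f"zero CWB variance for cells: {list(bad)[:10]}")
    out["cwb_z"] = (out[value_col] - mean) / sd
    return out


def cwb_z_panel(climate: pd.DataFrame, month, window) -> pd.DataFrame:
    """Climate table -> per cell-year z-scored windowed CWB (one call)."""
    return z_transform(integrate_cwb(compute_cwb(climate), month, window))
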