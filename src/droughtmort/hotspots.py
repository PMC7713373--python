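"""Hotspot mapping and drought-attributable mortality area accounting.

A hotspot is a cell-year where excess canopy mortality (fractional deviation
strictly greater than zero) co-occurs with drought (windowed CWB z-score
below the detected threshold).  Excess area is counted additively as
(observed - fitted) mortality rate x forest area, floored at zero, and summed
per year, per cell and in total, at the central threshold and at its lower
and upper credible bounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trend import PIXEL_AREA_HA

__all__ = ["AreaSummary", "map_hotspots", "summarize_area"]


@dataclass
class AreaSummary:
    """Drought-attributable excess-mortality area at the three thresholds."""

    totals: dict  # threshold -> total excess area (ha)
    annual: pd.DataFrame  # year x threshold, excess area (ha)
    cell_share: pd.DataFrame  # per cell: excess area and % of total mortality
    central: float

    def bounds_ordered(self):
        thrs = sorted(self.totals)  # most negative = strictest
        vals = [self.totals[t] for t in thrs]
        return all(a <= b + 1e-9 for a, b in zip(vals, vals[1:]))


def map_hotspots(deviation: pd.DataFrame, cwb_z: pd.DataFrame,
                 threshold=-1.6, bounds=(-2.0, -1.3),
                 pixel_area=PIXEL_AREA_HA) -> dict:
    """Flag hotspot cell-years at the central threshold and its bounds.

    ``deviation`` needs cell_id, year, mort, observed_rate, fitted_rate,
    forest_pixels (the output of :func:`droughtmort.trend.deviation_panel`);
    ``cwb_z`` needs cell_id, year, cwb_z on the same cell-years.  Returns
    ``{threshold: panel}`` with one panel per threshold, each carrying
    ``is_hotspot`` and the hotspot ``excess_area_ha``.
    """
    merged = deviation.merge(cwb_z[["cell_id", "year", "cwb_z"]],
                             on=["cell_id", "year"], how="left")
    if merged["cwb_z"].isna().any():
        bad = merged.loc[merged["cwb_z"].isna(), ["cell_id", "year"]]
        raise ValueError(
            "CWB panel does not cover cell-years: "
            + ", ".join(f"({r.cell_id}, {r.year})" for r in bad.head(10).itertuples())
        )
    excess_pixels = np.maximum(
        merged["observed_rate"] - merged["fitted_rate"], 0.0
    ) * merged["forest_pixels"]
    panels = {}
    for thr in sorted({float(threshold), *map(float, bounds)}):
        panel = merged[["cell_id", "year", "mort", "cwb_z"]].copy()
        panel["is_hotspot"] = (merged["mort"] > 0.0) & (merged["cwb_z"] < thr)
        panel["excess_area_ha"] = np.where(
            panel["is_hotspot"], excess_pixels * pixel_area, 0.0
        )
        panel["threshold_used"] = thr
        panels[thr] = panel
    return panels


def summarize_area(panels: dict, deviation: pd.DataFrame,
                   central=-1.6, pixel_area=PIXEL_AREA_HA) -> AreaSummary:
    """Annual, per-cell and total drought-attributable excess areas.

    The per-cell share is the hotspot excess area at the central threshold
    divided by the cell's total observed mortality area over the whole
    period, in percent; cells with zero total mortality get a missing share.
    Threshold monotonicity of the totals (stricter threshold -> smaller
    total) is asserted on every call.
    """
    central = float(central)
    if central not in panels:
        raise ValueError(f"central threshold {central} not among panels "
                         f"{sorted(panels)}")
    totals = {thr: float(p["excess_area_ha"].sum()) for thr, p in panels.items()}
    thrs = sorted(totals)
    for a, b in zip(thrs, thrs[1:]):
        if totals[a] > totals[b] + 1e-9:
            raise AssertionError(
                f"threshold monotonicity violated: total at {a} exceeds total at {b}"
            )
    annual = pd.DataFrame(
        {thr: p.groupby("year")["excess_area_ha"].sum() for thr, p in panels.items()}
    )

    mort_area = (
        deviation.assign(m=deviation["observed_rate"] * deviation["forest_pixels"]
                         * pixel_area)
        .groupby("cell_id")["m"].sum()
    )
    cell_excess = panels[central].groupby("cell_id")["excess_area_ha"].sum()
    share = pd.DataFrame({"excess_area_ha": cell_excess,
                          "total_mortality_ha": mort_area})
    with np.errstate(divide="ignore", invalid="ignore"):
        share["share_pct"] = np.where(
            share["total_mortality_ha"] > 0,
            100.0 * share["excess_area_ha"] / share["total_mortality_ha"],
            np.nan,
        )
    return AreaSummary(totals=totals, annual=annual, cell_share=share,
                       central=central)
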