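"""Canopy-height calibration against a reference canopy surface.

The raw CHM (surface model minus interpolated terrain) inherits a bias from
radar penetration into the canopy.  To correct it, both the raw CHM and an
independent reference canopy surface are averaged over non-overlapping
1 ha plots (10 x 10 pixels at 10 m, anchored at the raster origin), plots
with wildly inconsistent values are excluded (difference above twice the
99th percentile of absolute differences), and an ordinary least-squares
line ``reference = slope * raw + intercept`` supplies the correction.
Application removes raw values at or below 0 m, drops calibrated heights
not exceeding the minimum credible tree height (2.19 m by default) and
caps heights at the 99th percentile within each administrative division.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry.base import BaseGeometry

from .grid import RasterGrid
from .vector import rasterize_polygons

__all__ = [
    "CalibrationModel",
    "aggregate_plots",
    "exclude_outliers",
    "fit_calibration",
    "apply_calibration",
    "height_summary",
]

DEFAULT_MIN_HEIGHT_M = 2.19
DEFAULT_CAP_PERCENTILE = 99.0


@dataclass
class CalibrationModel:
    """Fitted linear height correction and its fit diagnostics."""

    slope: float
    intercept: float
    mae_before: float
    mae_after: float
    n_plots_used: int
    n_outliers_excluded: int
    min_height: float = DEFAULT_MIN_HEIGHT_M
    cap_percentile: float = DEFAULT_CAP_PERCENTILE

    def __post_init__(self) -> None:
        if self.min_height <= 0:
            raise ValueError("min_height must be positive")

    def transform(self, raw: np.ndarray) -> np.ndarray:
        return self.slope * raw + self.intercept

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def aggregate_plots(
    chm: RasterGrid,
    reference: RasterGrid,
    mask: RasterGrid,
    plot_size_m: float = 100.0,
) -> pd.DataFrame:
    """Mean raw and reference height per 1 ha plot, over tree pixels only.

    Plots are non-overlapping square tiles anchored at the raster origin;
    incomplete edge tiles are discarded, and tiles containing no tree pixel
    (or no valid height) are absent from the table.
    """
    chm.require_alignment(reference, "aggregate_plots")
    chm.require_alignment(mask, "aggregate_plots")
    tile = int(round(plot_size_m / chm.pixel_size))
    if tile < 1:
        raise ValueError("plot size is below one pixel")
    nrow, ncol = chm.shape
    n_tr, n_tc = nrow // tile, ncol // tile
    if n_tr == 0 or n_tc == 0:
        raise ValueError(
            f"extent {chm.shape} holds no complete {tile}x{tile}-pixel plot"
        )

    keep = (mask.data == 1) & chm.valid_mask() & reference.valid_mask()
    raw = np.where(keep, chm.data.astype(float), 0.0)
    ref = np.where(keep, reference.data.astype(float), 0.0)

    def _block(a: np.ndarray) -> np.ndarray:
        return a[: n_tr * tile, : n_tc * tile].reshape(n_tr, tile, n_tc, tile).sum(axis=(1, 3))

    n_pix = _block(keep.astype(float))
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_raw = _block(raw) / n_pix
        mean_ref = _block(ref) / n_pix
    rows, cols = np.nonzero(n_pix > 0)
    return pd.DataFrame(
        {
            "plot_id": rows * n_tc + cols,
            "plot_row": rows,
            "plot_col": cols,
            "mean_raw_height": mean_raw[rows, cols],
            "mean_reference_height": mean_ref[rows, cols],
            "n_tree_pixels": n_pix[rows, cols].astype(int),
        }
    )


def exclude_outliers(plots: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop plots whose surface disagreement is anomalously large.

    A plot is excluded when ``|reference - raw|`` exceeds twice the 99th
    percentile of that absolute difference over all plots.  Returns the
    retained plots and the number excluded.
    """
    if len(plots) < 2:
        raise ValueError("need at least two plots to screen outliers")
    diff = (plots["mean_reference_height"] - plots["mean_raw_height"]).abs()
    cutoff = 2.0 * np.percentile(diff, 99)
    keep = diff <= cutoff
    return plots.loc[keep].reset_index(drop=True), int((~keep).sum())


def fit_calibration(
    plots: pd.DataFrame,
    *,
    screen_outliers: bool = True,
    min_height: float = DEFAULT_MIN_HEIGHT_M,
    cap_percentile: float = DEFAULT_CAP_PERCENTILE,
) -> CalibrationModel:
    """Ordinary least-squares height correction from plot pairs.

    Fits ``reference ~ slope * raw + intercept`` and records the mean
    absolute error before (identity line) and after the correction on the
    fitting plots; least-squares optimality guarantees no MAE increase in
    practice and the residual-mean property keeps the fit unbiased.
    """
    n_out = 0
    if screen_outliers:
        plots, n_out = exclude_outliers(plots)
    if len(plots) < 3:
        raise ValueError("need at least three plots after outlier screening")
    raw = plots["mean_raw_height"].to_numpy(float)
    ref = plots["mean_reference_height"].to_numpy(float)
    if np.ptp(raw) == 0:
        raise ValueError("raw plot heights are constant; slope is undetermined")
    fit = stats.linregress(raw, ref)
    mae_before = float(np.mean(np.abs(ref - raw)))
    mae_after = float(np.mean(np.abs(ref - (fit.slope * raw + fit.intercept))))
    return CalibrationModel(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        mae_before=mae_before,
        mae_after=mae_after,
        n_plots_used=len(plots),
        n_outliers_excluded=n_out,
        min_height=min_height,
        cap_percentile=cap_percentile,
    )


def apply_calibration(
    chm: RasterGrid,
    model: CalibrationModel,
    division_zones: Mapping[str, BaseGeometry] | None = None,
) -> RasterGrid:
    """Correct the raw CHM and enforce the height plausibility rules.

    Raw values at or below 0 m are removed before the transform; calibrated
    heights must exceed ``model.min_height`` to survive; surviving heights
    are clipped to the ``model.cap_percentile`` percentile computed within
    each division (globally for pixels outside every division polygon).
    """
    raw = chm.data.astype(float)
    alive = chm.valid_mask() & (raw > 0)
    cal = np.where(alive, model.transform(raw), np.nan)
    alive &= cal > model.min_height
    cal[~alive] = np.nan

    if division_zones:
        zones, _ = rasterize_polygons(chm, division_zones)
    else:
        zones = np.zeros(chm.shape, dtype=np.int32)
    if (zones[alive] == 0).any() and division_zones:
        warnings.warn(
            "pixels outside every division polygon are capped with the global percentile",
            stacklevel=2,
        )
    for zid in np.unique(zones[alive]) if alive.any() else []:
        sel = alive & (zones == zid)
        cap = np.percentile(cal[sel], model.cap_percentile)
        cal[sel] = np.minimum(cal[sel], cap)
    return chm.with_data(cal, nodata=float("nan"))


def height_summary(
    chm: RasterGrid,
    division_zones: Mapping[str, BaseGeometry],
    fra_threshold: float = 5.0,
) -> pd.DataFrame:
    """Per-division height statistics of a calibrated CHM.

    Reports the mean and maximum height plus the mean restricted to trees
    taller than ``fra_threshold`` (5 m, the conventional forest-definition
    minimum).  Divisions containing no valid height yield a blank row.
    """
    zones, names = rasterize_polygons(chm, division_zones)
    valid = chm.valid_mask()
    h = chm.data.astype(float)
    rows = []
    for zid, name in enumerate(names, start=1):
        sel = valid & (zones == zid)
        if not sel.any():
            warnings.warn(f"division {name!r} holds no valid canopy height", stacklevel=2)
            rows.append({"division": name, "mean_m": np.nan, "max_m": np.nan,
                         "mean_above_threshold_m": np.nan, "n_pixels": 0})
            continue
        vals = h[sel]
        tall = vals[vals > fra_threshold]
        rows.append(
            {
                "division": name,
                "mean_m": float(vals.mean()),
                "max_m": float(vals.max()),
                "mean_above_threshold_m": float(tall.mean()) if tall.size else np.nan,
                "n_pixels": int(vals.size),
            }
        )
    return pd.DataFrame(rows)
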