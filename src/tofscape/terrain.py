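"""Bare-earth terrain interpolation and canopy-height differencing.

The canopy height model (CHM) is the difference between a digital surface
model (DSM, top of canopy) and a digital terrain model (DTM, bare earth).
In flat agricultural landscapes the DTM can be built by inverse-distance
weighting (IDW) of bare-ground control points (GCPs), holding out an
independent point set to report an RMSE for the interpolated surface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .grid import RasterGrid

__all__ = [
    "GCPSet",
    "DtmResult",
    "idw_interpolate",
    "validate_dtm",
    "canopy_height",
    "build_dtm",
]


@dataclass
class GCPSet:
    """Bare-ground control points: planar coordinates and elevation (m)."""

    x: np.ndarray
    y: np.ndarray
    elevation: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.atleast_1d(np.asarray(self.x, dtype=float))
        self.y = np.atleast_1d(np.asarray(self.y, dtype=float))
        self.elevation = np.atleast_1d(np.asarray(self.elevation, dtype=float))
        if not (self.x.size == self.y.size == self.elevation.size):
            raise ValueError("x, y and elevation must have equal length")

    def __len__(self) -> int:
        return self.x.size

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"x": self.x, "y": self.y, "elevation_m": self.elevation}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "GCPSet":
        df = pd.read_csv(path)
        return cls(x=df["x"].to_numpy(), y=df["y"].to_numpy(), elevation=df["elevation_m"].to_numpy())


@dataclass
class DtmResult:
    """An interpolated terrain surface and its holdout validation."""

    dtm: RasterGrid
    rmse_holdout: float
    n_gcp: int
    n_holdout: int
    idw_power: float
    search_radius: float | None  # None = all points contribute

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "rmse_holdout_m": self.rmse_holdout,
                    "n_gcp": self.n_gcp,
                    "n_holdout": self.n_holdout,
                    "idw_power": self.idw_power,
                    "search_radius_m": self.search_radius,
                }
            )
        )


def idw_interpolate(
    gcps: GCPSet,
    like: RasterGrid,
    power: float = 2.0,
    radius: float | None = None,
    *,
    chunk: int = 4096,
) -> RasterGrid:
    """Inverse-distance-weighted surface from GCP elevations.

    Each cell center receives ``sum(w_i z_i) / sum(w_i)`` with
    ``w_i = d_i ** -power`` over the GCPs within ``radius`` (all GCPs when
    ``radius`` is None).  A cell coinciding with a GCP (distance below
    1e-6 of a pixel) takes that GCP's elevation exactly.  Cells with no GCP
    in range become NaN nodata.
    """
    if len(gcps) == 0:
        raise ValueError("cannot interpolate from an empty GCP set")
    if power <= 0:
        raise ValueError("IDW power must be positive")

    xs, ys = like.cell_centers()
    qx, qy = xs.ravel(), ys.ravel()
    pts = np.column_stack([gcps.x, gcps.y])
    z = gcps.elevation
    eps = 1e-6 * like.pixel_size
    out = np.full(qx.size, np.nan)

    for start in range(0, qx.size, chunk):
        sl = slice(start, min(start + chunk, qx.size))
        dx = qx[sl, None] - pts[None, :, 0]
        dy = qy[sl, None] - pts[None, :, 1]
        d = np.hypot(dx, dy)
        coincident = d < eps
        with np.errstate(divide="ignore"):
            w = d ** (-power)
        w[coincident] = 0.0  # handled exactly below
        if radius is not None:
            w[d > radius] = 0.0
        wsum = w.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = (w @ z) / wsum
        vals[wsum == 0] = np.nan  # no GCP in range
        hit_rows, hit_cols = np.nonzero(coincident)
        vals[hit_rows] = z[hit_cols]
        out[sl] = vals

    return like.with_data(out.reshape(like.shape), nodata=float("nan"))


def validate_dtm(dtm: RasterGrid, holdout: GCPSet) -> tuple[float, int]:
    """RMSE of the DTM against holdout GCP elevations.

    Points falling on nodata cells (or outside the grid) are excluded from
    the RMSE; the count of excluded points is returned alongside.
    """
    if len(holdout) == 0:
        raise ValueError("holdout set is empty")
    rows, cols = dtm.xy_to_rowcol(holdout.x, holdout.y)
    nrow, ncol = dtm.shape
    inside = (rows >= 0) & (rows < nrow) & (cols >= 0) & (cols < ncol)
    pred = np.full(len(holdout), np.nan)
    pred[inside] = dtm.data[rows[inside], cols[inside]]
    usable = inside & ~np.isnan(pred)
    n_excluded = int((~usable).sum())
    if not usable.any():
        raise ValueError("no holdout point falls on a valid DTM cell")
    err = pred[usable] - holdout.elevation[usable]
    return float(np.sqrt(np.mean(err**2))), n_excluded


def build_dtm(
    gcps: GCPSet,
    holdout: GCPSet,
    like: RasterGrid,
    power: float = 2.0,
    radius: float | None = None,
) -> DtmResult:
    """Interpolate the DTM and validate it on the holdout set in one step."""
    dtm = idw_interpolate(gcps, like, power=power, radius=radius)
    rmse, _ = validate_dtm(dtm, holdout)
    return DtmResult(
        dtm=dtm,
        rmse_holdout=rmse,
        n_gcp=len(gcps),
        n_holdout=len(holdout),
        idw_power=power,
        search_radius=radius,
    )


def canopy_height(dsm: RasterGrid, dtm: RasterGrid, tof_mask: RasterGrid) -> RasterGrid:
    """Raw canopy height: DSM minus DTM restricted to the tree mask.

    Negative differences are retained here; the calibration stage removes
    heights at or below zero before fitting its correction.
    """
    dsm.require_alignment(dtm, "canopy_height")
    dsm.require_alignment(tof_mask, "canopy_height")
    keep = (tof_mask.data == 1) & dsm.valid_mask() & dtm.valid_mask()
    chm = np.where(keep, dsm.data.astype(float) - dtm.data.astype(float), np.nan)
    return dsm.with_data(chm, nodata=float("nan"))
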