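"""Multi-date compositing: greenest-pixel optical mosaics and SAR averaging.

Optical collections are reduced per pixel to the acquisition date with the
highest NDVI ("greenest" or quality mosaic), carrying every band from that
date.  SAR collections are averaged over time in the linear power domain —
never in dB — and the descending average has its inter-swath scan-line gaps
filled from the ascending average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import RasterGrid, SceneCollection

__all__ = [
    "OpticalComposite",
    "SarComposite",
    "compute_ndvi",
    "greenest_composite",
    "temporal_average_sar",
    "fill_scan_lines",
    "composite_sar",
]

DEFAULT_SCANLINE_THRESHOLD_DB = -25.0


@dataclass
class OpticalComposite:
    """Per-band grids selected at each pixel's greenest date, plus NDVI."""

    bands: dict[str, RasterGrid]
    ndvi: RasterGrid
    source_date_index: RasterGrid  # int index into the collection's date list


@dataclass
class SarComposite:
    """Temporal-mean backscatter in dB with the scan-line fill flag."""

    vh_db: RasterGrid
    vv_db: RasterGrid
    fill_flag: RasterGrid  # uint8, 1 where the descending pixel was donor-filled


def compute_ndvi(red: RasterGrid, nir: RasterGrid) -> RasterGrid:
    """Normalized difference vegetation index (NIR - red)/(NIR + red).

    Nodata where either input is nodata or both reflectances are zero.
    """
    red.require_alignment(nir, "compute_ndvi")
    r = red.data.astype(float)
    n = nir.data.astype(float)
    valid = red.valid_mask() & nir.valid_mask()
    if (r[valid] < 0).any() or (n[valid] < 0).any():
        raise ValueError("reflectances must be non-negative")
    denom = n + r
    good = valid & (denom > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ndvi = np.where(good, (n - r) / denom, np.nan)
    return red.with_data(ndvi, nodata=float("nan"))


def greenest_composite(collection: SceneCollection) -> OpticalComposite:
    """Select, per pixel, every band from the date maximizing NDVI.

    Ties break toward the earliest date; pixels with no valid date at all
    are nodata throughout.  Compositing a single-date collection is the
    identity, and the operation is idempotent.
    """
    if len(collection) == 0:
        raise ValueError("cannot composite an empty collection")
    for b in ("red", "nir"):
        if b not in collection.bands:
            raise ValueError(f"collection lacks required band {b!r}")
    like = collection.reference
    ndvi_stack = np.stack(
        [
            compute_ndvi(collection.grids[d]["red"], collection.grids[d]["nir"]).data
            for d in collection.dates
        ]
    )
    # argmax over dates ignoring NaN; all-NaN pixels flagged nodata
    all_nan = np.isnan(ndvi_stack).all(axis=0)
    filled = np.where(np.isnan(ndvi_stack), -np.inf, ndvi_stack)
    best = filled.argmax(axis=0)  # argmax returns the first (earliest) maximum
    rows, cols = np.indices(like.shape)
    bands = {}
    for b in collection.bands:
        stack = collection.band_stack(b).astype(float)
        data = stack[best, rows, cols]
        data[all_nan] = np.nan
        bands[b] = like.with_data(data, nodata=float("nan"))
    ndvi = ndvi_stack[best, rows, cols]
    ndvi[all_nan] = np.nan
    best_out = best.astype(np.int16)
    best_out[all_nan] = -1
    return OpticalComposite(
        bands=bands,
        ndvi=like.with_data(ndvi, nodata=float("nan")),
        source_date_index=like.with_data(best_out, nodata=-1),
    )


def temporal_average_sar(collection: SceneCollection, band: str) -> RasterGrid:
    """Temporal mean of backscatter, computed in the linear power domain.

    dB values are converted to power (10^(dB/10)), averaged over the valid
    dates per pixel, and re-expressed as 10*log10(mean).  Averaging in dB
    would underestimate the mean (Jensen's inequality) and is deliberately
    not what this does.
    """
    if len(collection) == 0:
        raise ValueError("cannot average an empty collection")
    if band not in collection.bands:
        raise ValueError(f"unknown band {band!r}; have {collection.bands}")
    stack = collection.band_stack(band).astype(float)
    valid = np.stack([collection.grids[d][band].valid_mask() for d in collection.dates])
    power = np.where(valid, 10.0 ** (stack / 10.0), np.nan)
    with np.errstate(invalid="ignore"):
        mean_power = np.nanmean(power, axis=0)
    any_valid = valid.any(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(any_valid, 10.0 * np.log10(mean_power), np.nan)
    return collection.reference.with_data(out, nodata=float("nan"))


def fill_scan_lines(
    descending_mean: RasterGrid,
    ascending_mean: RasterGrid,
    low_db_threshold: float = DEFAULT_SCANLINE_THRESHOLD_DB,
) -> tuple[RasterGrid, RasterGrid]:
    """Fill inter-swath scan-line gaps in the descending average.

    Pixels whose descending value is below the threshold (or nodata) take
    the ascending value and are flagged; the ascending image is the only
    donor, so a still-low donor value is kept as-is but flagged.
    """
    descending_mean.require_alignment(ascending_mean, "fill_scan_lines")
    desc = descending_mean.data.astype(float)
    asc = ascending_mean.data.astype(float)
    bad = ~descending_mean.valid_mask() | (desc < low_db_threshold)
    out = np.where(bad, asc, desc)
    flag = bad.astype(np.uint8)
    return (
        descending_mean.with_data(out, nodata=float("nan")),
        descending_mean.with_data(flag, nodata=255),
    )


def composite_sar(
    ascending: SceneCollection,
    descending: SceneCollection,
    low_db_threshold: float = DEFAULT_SCANLINE_THRESHOLD_DB,
) -> SarComposite:
    """Average both passes per polarization and gap-fill the descending mean."""
    filled = {}
    flag = None
    for band in ("VH", "VV"):
        asc_mean = temporal_average_sar(ascending, band)
        desc_mean = temporal_average_sar(descending, band)
        filled[band], band_flag = fill_scan_lines(desc_mean, asc_mean, low_db_threshold)
        flag = band_flag if flag is None else flag.with_data(
            np.maximum(flag.data, band_flag.data), nodata=255
        )
    return SarComposite(vh_db=filled["VH"], vv_db=filled["VV"], fill_flag=flag)
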