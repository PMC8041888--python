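"""Tree-extent classification by optical-radar threshold fusion.

A pixel is a tree when it is simultaneously photosynthetic (NDVI strictly
inside the 0.3-0.9 window on the greenest composite) and structural
(temporal-mean VH in [-14, -9] dB — volumetric canopy scattering — with VV
in [-8, -2] dB vetoing bare/urban false positives).  Contiguous forest is
then removed with a polygon exclusion mask, and clumps smaller than 25
pixels (0.25 ha at 10 m) are sieved out.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import yaml
from shapely.geometry.base import BaseGeometry
from skimage import measure

from .grid import RasterGrid
from .vector import polygon_mask

__all__ = [
    "ThresholdConfig",
    "threshold_optical",
    "threshold_sar",
    "fuse",
    "apply_exclusion",
    "sieve",
    "classify_tof",
]

MASK_NODATA = 255


@dataclass
class ThresholdConfig:
    """Decision thresholds for the fusion classifier.

    NDVI bounds are exclusive; SAR windows are inclusive ranges.  The sieve
    removes 8-connected clumps below ``min_patch_pixels`` (edge-or-corner
    adjacency; set ``sieve_corner_connectivity`` False for edge-only).
    """

    ndvi_low: float = 0.3
    ndvi_high: float = 0.9
    vh_low: float = -14.0
    vh_high: float = -9.0
    vv_low: float = -8.0
    vv_high: float = -2.0
    min_patch_pixels: int = 25
    sieve_corner_connectivity: bool = True

    def __post_init__(self) -> None:
        for lo, hi in (
            (self.ndvi_low, self.ndvi_high),
            (self.vh_low, self.vh_high),
            (self.vv_low, self.vv_high),
        ):
            if lo >= hi:
                raise ValueError(f"threshold window must satisfy low < high, got [{lo}, {hi}]")
        if self.min_patch_pixels < 1:
            raise ValueError("min_patch_pixels must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "ThresholdConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)


def _mask_grid(src: RasterGrid, ones: np.ndarray, invalid: np.ndarray) -> RasterGrid:
    out = np.where(ones, 1, 0).astype(np.uint8)
    out[invalid] = MASK_NODATA
    return src.with_data(out, nodata=MASK_NODATA)


def threshold_optical(ndvi: RasterGrid, cfg: ThresholdConfig = ThresholdConfig()) -> RasterGrid:
    """Photosynthetic mask: 1 iff ndvi_low < NDVI < ndvi_high (exclusive)."""
    valid = ndvi.valid_mask()
    v = ndvi.data.astype(float)
    ones = valid & (v > cfg.ndvi_low) & (v < cfg.ndvi_high)
    return _mask_grid(ndvi, ones, ~valid)


def threshold_sar(
    vh_db: RasterGrid, vv_db: RasterGrid, cfg: ThresholdConfig = ThresholdConfig()
) -> RasterGrid:
    """Structural mask: VH and VV both inside their inclusive dB windows."""
    vh_db.require_alignment(vv_db, "threshold_sar")
    valid = vh_db.valid_mask() & vv_db.valid_mask()
    vh = vh_db.data.astype(float)
    vv = vv_db.data.astype(float)
    ones = (
        valid
        & (vh >= cfg.vh_low) & (vh <= cfg.vh_high)
        & (vv >= cfg.vv_low) & (vv <= cfg.vv_high)
    )
    return _mask_grid(vh_db, ones, ~valid)


def fuse(optical: RasterGrid, sar: RasterGrid) -> RasterGrid:
    """Logical AND of the photosynthetic and structural masks."""
    optical.require_alignment(sar, "fuse")
    invalid = ~optical.valid_mask() | ~sar.valid_mask()
    ones = (optical.data == 1) & (sar.data == 1) & ~invalid
    return _mask_grid(optical, ones, invalid)


def apply_exclusion(mask: RasterGrid, polygons: Sequence[BaseGeometry]) -> RasterGrid:
    """Zero out pixels whose centers fall inside any exclusion polygon."""
    if not polygons:
        return mask
    inside = polygon_mask(mask, polygons)
    out = mask.data.copy()
    out[inside & (out == 1)] = 0
    return mask.with_data(out)


def sieve(mask: RasterGrid, cfg: ThresholdConfig = ThresholdConfig()) -> RasterGrid:
    """Drop connected clumps smaller than ``min_patch_pixels``."""
    binary = mask.data == 1
    connectivity = 2 if cfg.sieve_corner_connectivity else 1
    labels = measure.label(binary, connectivity=connectivity)
    counts = np.bincount(labels.ravel())
    small = counts < cfg.min_patch_pixels
    small[0] = False
    out = mask.data.copy()
    out[small[labels]] = 0
    return mask.with_data(out)


def classify_tof(
    ndvi: RasterGrid,
    vh_db: RasterGrid,
    vv_db: RasterGrid,
    exclusion: Sequence[BaseGeometry] = (),
    cfg: ThresholdConfig = ThresholdConfig(),
) -> RasterGrid:
    """Full fusion chain: thresholds -> AND -> forest exclusion -> sieve."""
    optical = threshold_optical(ndvi, cfg)
    structural = threshold_sar(vh_db, vv_db, cfg)
    fused = fuse(optical, structural)
    cleaned = apply_exclusion(fused, exclusion)
    return sieve(cleaned, cfg)
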