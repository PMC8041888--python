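"""Raster and scene containers.

A :class:`RasterGrid` is the package's universal raster currency: a 2-D numpy
array plus a north-up geotransform (x/y origin of the top-left corner and a
square pixel size in metres), a nodata marker and a free-form CRS tag.  Grids
are written as plain single-band TIFF with the geotransform, nodata value and
CRS serialised into the ImageDescription tag as JSON, so files round-trip
without external geospatial bindings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import tifffile

__all__ = ["RasterGrid", "SceneCollection", "read_geotiff", "GridAlignmentError"]


class GridAlignmentError(ValueError):
    """Raised when an operation receives grids that are not co-registered."""


@dataclass(frozen=True)
class RasterGrid:
    """A single-band raster with georeferencing metadata.

    Parameters
    ----------
    data:
        2-D array of values. Float grids use NaN-compatible ``nodata``;
        integer grids use a sentinel (e.g. 255 for uint8 masks).
    origin:
        ``(x, y)`` of the top-left corner of the top-left pixel, metres.
    pixel_size:
        Square pixel edge length in metres (north-up grid).
    nodata:
        Marker for missing values, or ``None`` if all pixels are valid.
    crs:
        Free-form tag, e.g. ``"EPSG:32646"`` or ``"synthetic-planar"``.
    """

    data: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)
    pixel_size: float = 10.0
    nodata: float | int | None = None
    crs: str = "synthetic-planar"

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 2:
            raise ValueError(f"RasterGrid data must be 2-D, got shape {arr.shape}")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")
        object.__setattr__(self, "data", arr)

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def pixel_area_ha(self) -> float:
        """Area of one pixel in hectares (10 m pixels -> 0.01 ha)."""
        return self.pixel_size**2 / 10_000.0

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """X and Y coordinates of every pixel center as 2-D arrays."""
        nrow, ncol = self.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(ncol) + 0.5) * self.pixel_size
        ys = y0 - (np.arange(nrow) + 0.5) * self.pixel_size
        return np.meshgrid(xs, ys)

    def xy_to_rowcol(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map world coordinates to (row, col) indices; no bounds check."""
        x0, y0 = self.origin
        col = np.floor((np.asarray(x) - x0) / self.pixel_size).astype(int)
        row = np.floor((y0 - np.asarray(y)) / self.pixel_size).astype(int)
        return row, col

    def same_geometry(self, other: "RasterGrid", *, atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and abs(self.pixel_size - other.pixel_size) <= atol
            and abs(self.origin[0] - other.origin[0]) <= atol
            and abs(self.origin[1] - other.origin[1]) <= atol
        )

    def require_alignment(self, other: "RasterGrid", what: str = "operation") -> None:
        if not self.same_geometry(other):
            raise GridAlignmentError(
                f"{what}: grids are not co-registered "
                f"(shapes {self.shape} vs {other.shape}, "
                f"origins {self.origin} vs {other.origin}, "
                f"pixel sizes {self.pixel_size} vs {other.pixel_size})"
            )

    # -- values -----------------------------------------------------------
    def valid_mask(self) -> np.ndarray:
        """Boolean array, True where the pixel holds a real value."""
        if self.nodata is None:
            if np.issubdtype(self.data.dtype, np.floating):
                return ~np.isnan(self.data)
            return np.ones(self.shape, dtype=bool)
        if isinstance(self.nodata, float) and np.isnan(self.nodata):
            return ~np.isnan(self.data)
        out = self.data != self.nodata
        if np.issubdtype(self.data.dtype, np.floating):
            out &= ~np.isnan(self.data)
        return out

    def with_data(self, data: np.ndarray, *, nodata: float | int | None = "unchanged") -> "RasterGrid":
        """Copy of this grid carrying new data (same georeferencing)."""
        kwargs = {"data": data}
        if nodata != "unchanged":
            kwargs["nodata"] = nodata
        return replace(self, **kwargs)

    # -- I/O --------------------------------------------------------------
    def write(self, path: str | Path) -> None:
        meta = {
            "origin": list(self.origin),
            "pixel_size": self.pixel_size,
            "nodata": None if self.nodata is None or (isinstance(self.nodata, float) and np.isnan(self.nodata)) else self.nodata,
            "nodata_is_nan": isinstance(self.nodata, float) and bool(np.isnan(self.nodata)),
            "crs": self.crs,
        }
        tifffile.imwrite(Path(path), self.data, description=json.dumps(meta))


def read_geotiff(path: str | Path) -> RasterGrid:
    """Read a raster written by :meth:`RasterGrid.write`."""
    with tifffile.TiffFile(Path(path)) as tf:
        page = tf.pages[0]
        data = page.asarray()
        desc = page.tags.get("ImageDescription")
        meta = json.loads(desc.value) if desc is not None else {}
    nodata = meta.get("nodata")
    if meta.get("nodata_is_nan"):
        nodata = float("nan")
    return RasterGrid(
        data=data,
        origin=tuple(meta.get("origin", (0.0, 0.0))),
        pixel_size=float(meta.get("pixel_size", 10.0)),
        nodata=nodata,
        crs=meta.get("crs", "unknown"),
    )


@dataclass
class SceneCollection:
    """An ordered, co-registered stack of single-band acquisitions.

    Optical collections carry one entry per (date, band) pair; SAR collections
    one entry per (date, polarization).  ``grids[date][band]`` holds the
    :class:`RasterGrid` for that acquisition.
    """

    dates: list[str]
    bands: list[str]
    grids: dict[str, dict[str, RasterGrid]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ref = None
        for date in self.dates:
            for band in self.bands:
                g = self.grids[date][band]
                if ref is None:
                    ref = g
                else:
                    ref.require_alignment(g, "SceneCollection")

    def __len__(self) -> int:
        return len(self.dates)

    def __iter__(self) -> Iterator[tuple[str, dict[str, RasterGrid]]]:
        for date in self.dates:
            yield date, self.grids[date]

    @property
    def reference(self) -> RasterGrid:
        return self.grids[self.dates[0]][self.bands[0]]

    def band_stack(self, band: str) -> np.ndarray:
        """(n_dates, rows, cols) array for one band, in date order."""
        return np.stack([self.grids[d][band].data for d in self.dates])

    @classmethod
    def from_arrays(
        cls,
        dates: Sequence[str],
        bands: Sequence[str],
        arrays: dict[str, dict[str, np.ndarray]],
        *,
        like: RasterGrid,
        nodata: float | None = None,
    ) -> "SceneCollection":
        grids = {
            d: {b: like.with_data(arrays[d][b], nodata=nodata) for b in bands}
            for d in dates
        }
        return cls(dates=list(dates), bands=list(bands), grids=grids)
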