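"""Patch structure of the tree-extent mask.

Patches ("stands") are 4-connected components — pixels joined by at least
one shared edge — of the binary tree mask.  The size distribution uses the
standard national-reporting bins: (0,1], (1,5], (5,10], (10,100],
(100,1000], (1000,10000] and (10000,100000] hectares.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage import measure

from .grid import RasterGrid

__all__ = [
    "SIZE_CLASS_EDGES",
    "SIZE_CLASS_LABELS",
    "label_patches",
    "patch_table",
    "size_class_summary",
    "summary_from_counts",
]

SIZE_CLASS_EDGES = (0.0, 1.0, 5.0, 10.0, 100.0, 1_000.0, 10_000.0, 100_000.0)
SIZE_CLASS_LABELS = (
    "<=1 ha",
    "1-5 ha",
    "5-10 ha",
    "10-100 ha",
    "100-1000 ha",
    "1000-10000 ha",
    "10000-100000 ha",
)


def label_patches(mask: RasterGrid) -> RasterGrid:
    """Label 4-connected (edge-only) components 1..K; background 0.

    Diagonal-only contact does not join patches.
    """
    labels = measure.label(mask.data == 1, connectivity=1).astype(np.int32)
    return mask.with_data(labels, nodata=None)


def patch_table(labels: RasterGrid, pixel_area_ha: float | None = None) -> pd.DataFrame:
    """One row per patch: pixel count, area (ha) and size class.

    ``pixel_area_ha`` defaults to the grid's own pixel area (0.01 ha at
    10 m).  Bins are lower-exclusive/upper-inclusive, with the first bin
    (0, 1] ha.
    """
    if pixel_area_ha is None:
        pixel_area_ha = labels.pixel_area_ha
    if pixel_area_ha <= 0:
        raise ValueError("pixel_area_ha must be positive")
    counts = np.bincount(labels.data.ravel())
    ids = np.arange(1, counts.size)
    pixel_count = counts[1:]
    present = pixel_count > 0
    df = pd.DataFrame(
        {"patch_id": ids[present], "pixel_count": pixel_count[present]}
    )
    df["area_ha"] = df["pixel_count"] * pixel_area_ha
    df["size_class"] = pd.cut(
        df["area_ha"],
        bins=SIZE_CLASS_EDGES,
        labels=SIZE_CLASS_LABELS,
        right=True,
        include_lowest=False,
    )
    return df


def size_class_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Patch-count and area shares per size class.

    Returns one row per size class with ``n_patches``, ``pct_patches`` and
    ``pct_area``; each percentage column sums to 100 up to rounding.  An
    empty table yields an empty summary.
    """
    if table.empty:
        return pd.DataFrame(
            columns=["size_class", "n_patches", "area_ha", "pct_patches", "pct_area"]
        )
    grouped = table.groupby("size_class", observed=False).agg(
        n_patches=("patch_id", "size"), area_ha=("area_ha", "sum")
    )
    grouped = grouped.reindex(SIZE_CLASS_LABELS, fill_value=0).reset_index(
        names="size_class"
    )
    n_total = grouped["n_patches"].sum()
    a_total = grouped["area_ha"].sum()
    grouped["pct_patches"] = 100.0 * grouped["n_patches"] / n_total
    grouped["pct_area"] = 100.0 * grouped["area_ha"] / a_total if a_total > 0 else 0.0
    return grouped


def summary_from_counts(
    counts_per_class: dict[str, int], areas_per_class: dict[str, float] | None = None
) -> pd.DataFrame:
    """Size-class shares straight from per-class patch counts (and areas).

    Used when only the binned tallies of a national run are available
    rather than the patch-level table.
    """
    df = pd.DataFrame(
        {
            "size_class": list(counts_per_class),
            "n_patches": list(counts_per_class.values()),
        }
    )
    df["pct_patches"] = 100.0 * df["n_patches"] / df["n_patches"].sum()
    if areas_per_class is not None:
        df["area_ha"] = [areas_per_class[k] for k in counts_per_class]
        df["pct_area"] = 100.0 * df["area_ha"] / df["area_ha"].sum()
    return df
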