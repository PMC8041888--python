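"""Synthetic landscapes with known tree truth.

This module manufactures everything the downstream pipeline consumes —
multi-date optical reflectance, ascending/descending SAR backscatter, a
surface model pair and bare-ground control points — from a single
:class:`LandscapeTruth` with a known tree mask, tree heights and terrain.
It emulates a deltaic agricultural landscape: most land is flat cropland a
few metres above datum, and trees occur outside contiguous forest as three
patch archetypes — small homestead clusters around dwellings, narrow lines
along field boundaries, and long sinuous riparian corridors.

Everything is a pure function of (truth, params, seed): the same seed gives
bit-identical outputs, and no renderer mutates the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from shapely.geometry import box, Polygon
from skimage import measure

from .grid import RasterGrid, SceneCollection
from .terrain import GCPSet

__all__ = [
    "SceneParams",
    "LandscapeTruth",
    "generate_landscape",
    "render_optical_series",
    "render_sar_series",
    "render_dsm",
    "sample_gcps",
    "DIVISION_NAMES",
]

# Eight rectangular mock divisions (2 x 4 split of the scene) stand in for the
# eight administrative divisions a national run would supply as polygons.
DIVISION_NAMES = (
    "Barisal", "Chittagong", "Dhaka", "Khulna",
    "Mymensingh", "Rajshahi", "Rangpur", "Sylhet",
)

DEFAULT_OPTICAL_DATES = ("2018-02-05", "2018-02-20", "2018-03-07", "2018-03-22")
DEFAULT_SAR_DATES = (
    "2018-01-15", "2018-03-15", "2018-05-15",
    "2018-07-15", "2018-09-15", "2018-11-15",
)

SCANLINE_DB = -30.0  # backscatter assigned to inter-swath scan-line gaps


@dataclass
class SceneParams:
    """Knobs of the synthetic scene generator.

    Defaults describe the study conditions the pipeline is designed for:
    10 m pixels, a dry-season optical series, a year of SAR acquisitions in
    both pass directions, tree cover around 15% of the land surface, and a
    surface model whose canopy signal is biased low (slope 0.8) relative to
    true height, as X-band interferometric surface heights are in practice.
    """

    shape: tuple[int, int] = (256, 256)
    pixel_size: float = 10.0
    tree_fraction: float = 0.15
    archetype_weights: dict[str, float] = field(
        default_factory=lambda: {"homestead": 0.35, "field_boundary": 0.45, "riparian": 0.20}
    )
    optical_noise_sd: float = 0.05
    sar_speckle_sd_db: float = 1.5
    scanline_gap_fraction: float = 0.05
    dsm_noise_sd: float = 0.5
    reference_noise_sd: float = 0.3
    dsm_canopy_bias: tuple[float, float] = (0.8, 0.0)   # slope, intercept (m)
    reference_bias: tuple[float, float] = (1.0, 0.0)
    optical_dates: tuple[str, ...] = DEFAULT_OPTICAL_DATES
    sar_dates: tuple[str, ...] = DEFAULT_SAR_DATES
    cloud_fraction: float = 0.0
    terrain_base: float = 12.0        # m above datum; flat deltaic plain
    terrain_amplitude: float = 5.0    # sd of the smooth terrain undulation, m
    terrain_smoothness: float = 24.0  # gaussian smoothing length, pixels
    forest_fraction: float = 0.0      # contiguous-forest block to be excluded
    seed: int = 0

    def validate(self) -> None:
        nrow, ncol = self.shape
        if nrow <= 0 or ncol <= 0:
            raise ValueError(f"grid size must be positive, got {self.shape}")
        if nrow < 64 or ncol < 64:
            raise ValueError(f"grid must be at least 64x64, got {self.shape}")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")
        for name in ("tree_fraction", "scanline_gap_fraction", "cloud_fraction", "forest_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("optical_noise_sd", "sar_speckle_sd_db", "dsm_noise_sd", "reference_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.dsm_canopy_bias[0] <= 0:
            raise ValueError("DSM canopy bias slope must be > 0")
        if not self.optical_dates or not self.sar_dates:
            raise ValueError("at least one acquisition date is required per sensor")
        if sum(self.archetype_weights.values()) <= 0:
            raise ValueError("archetype weights must sum to a positive value")


@dataclass
class LandscapeTruth:
    """Ground truth for one synthetic scene.

    ``tree_mask`` marks every tree pixel (including any contiguous-forest
    block); ``tree_height`` is positive exactly there.  ``tof_mask`` is the
    trees-outside-forests truth: the tree mask with the forest-exclusion
    polygons removed, which is what the classification stage should recover
    after masking.
    """

    tree_mask: RasterGrid
    tree_height: RasterGrid
    terrain: RasterGrid
    division_polygons: dict[str, Polygon]
    forest_exclusion: list[Polygon]
    seed: int

    def tof_mask(self) -> RasterGrid:
        from .vector import polygon_mask

        data = self.tree_mask.data.copy()
        if self.forest_exclusion:
            data[polygon_mask(self.tree_mask, self.forest_exclusion)] = 0
        return self.tree_mask.with_data(data)


# ---------------------------------------------------------------------------
# patch archetypes

def _paint_homestead(mask: np.ndarray, rng: np.random.Generator) -> None:
    """3-10 px blob: a dwelling's tree cluster."""
    nrow, ncol = mask.shape
    r, c = rng.integers(1, nrow - 1), rng.integers(1, ncol - 1)
    n_px = int(rng.integers(3, 11))
    mask[r, c] = 1
    painted = 1
    while painted < n_px:
        dr, dc = rng.integers(-1, 2, size=2)
        r = int(np.clip(r + dr, 0, nrow - 1))
        c = int(np.clip(c + dc, 0, ncol - 1))
        if not mask[r, c]:
            mask[r, c] = 1
            painted += 1


def _paint_field_boundary(mask: np.ndarray, rng: np.random.Generator) -> None:
    """Straight 1-3 px wide line, 10-40 px long: trees on a field edge."""
    nrow, ncol = mask.shape
    length = int(rng.integers(10, 41))
    width = int(rng.integers(1, 4))
    r0, c0 = rng.integers(0, nrow), rng.integers(0, ncol)
    angle = rng.choice([0.0, np.pi / 2, np.pi / 4, 3 * np.pi / 4])
    dr, dc = np.sin(angle), np.cos(angle)
    for t in range(length):
        r = int(round(r0 + t * dr))
        c = int(round(c0 + t * dc))
        if not (0 <= r < nrow and 0 <= c < ncol):
            break
        mask[r : r + width, c : c + width] = 1


def _paint_riparian(mask: np.ndarray, rng: np.random.Generator) -> None:
    """Long sinuous corridor, 2-4 px wide: tree-lined river bank."""
    nrow, ncol = mask.shape
    length = int(rng.integers(60, 201))
    width = int(rng.integers(2, 5))
    r = float(rng.integers(0, nrow))
    c = float(rng.integers(0, ncol))
    heading = rng.uniform(0, 2 * np.pi)
    for _ in range(length):
        heading += rng.normal(0.0, 0.25)  # momentum keeps the corridor sinuous
        r += np.sin(heading)
        c += np.cos(heading)
        ri, ci = int(round(r)), int(round(c))
        if not (0 <= ri < nrow and 0 <= ci < ncol):
            break
        mask[max(0, ri) : ri + width, max(0, ci) : ci + width] = 1


_ARCHETYPES = {
    "homestead": _paint_homestead,
    "field_boundary": _paint_field_boundary,
    "riparian": _paint_riparian,
}


def _division_boxes(params: SceneParams) -> dict[str, Polygon]:
    """Partition the scene into a 2 x 4 grid of rectangular divisions."""
    nrow, ncol = params.shape
    px = params.pixel_size
    width, height = ncol * px, nrow * px
    col_edges = np.linspace(0.0, width, 5)
    row_edges = np.linspace(0.0, height, 3)  # y decreases downward from origin y0 = height
    out: dict[str, Polygon] = {}
    k = 0
    for i in range(2):
        for j in range(4):
            y_top = height - row_edges[i]
            y_bot = height - row_edges[i + 1]
            out[DIVISION_NAMES[k]] = box(col_edges[j], y_bot, col_edges[j + 1], y_top)
            k += 1
    return out


def generate_landscape(params: SceneParams) -> LandscapeTruth:
    """Build a landscape with known tree truth from :class:`SceneParams`.

    Tree patches are placed archetype by archetype until the requested tree
    fraction is reached; on grids of 256 pixels a side and larger, the
    realized fraction lands within about 20% (relative) of the request.
    """
    params.validate()
    rng = np.random.default_rng([int(params.seed), 0])
    nrow, ncol = params.shape
    n_px = nrow * ncol

    # smooth terrain: low-pass filtered white noise scaled to the target sd
    raw = ndimage.gaussian_filter(
        rng.standard_normal(params.shape), sigma=params.terrain_smoothness, mode="reflect"
    )
    sd = raw.std()
    terrain = params.terrain_base + (
        params.terrain_amplitude * raw / sd if sd > 0 else raw
    )

    # place patches until the target tree count is reached
    mask = np.zeros(params.shape, dtype=np.uint8)
    names = list(params.archetype_weights)
    weights = np.array([params.archetype_weights[n] for n in names], dtype=float)
    weights /= weights.sum()
    target = int(round(params.tree_fraction * n_px))
    max_draws = 50 * max(1, target)
    draws = 0
    while mask.sum() < target and draws < max_draws:
        _ARCHETYPES[rng.choice(names, p=weights)](mask, rng)
        draws += 1

    # optional contiguous-forest block in one corner, excluded downstream
    forest_polys: list[Polygon] = []
    if params.forest_fraction > 0:
        f_rows = int(round(np.sqrt(params.forest_fraction) * nrow))
        f_cols = int(round(np.sqrt(params.forest_fraction) * ncol))
        if f_rows > 0 and f_cols > 0:
            mask[:f_rows, :f_cols] = 1
            px = params.pixel_size
            height = nrow * px
            forest_polys.append(box(0.0, height - f_rows * px, f_cols * px, height))

    # per-patch base height plus smooth within-patch variation
    heights = np.zeros(params.shape, dtype=float)
    labels = measure.label(mask, connectivity=2)
    n_patches = labels.max()
    if n_patches:
        base = rng.uniform(4.0, 16.0, size=n_patches + 1)
        base[0] = 0.0
        texture = ndimage.gaussian_filter(rng.standard_normal(params.shape), sigma=3.0)
        heights = np.where(mask > 0, np.clip(base[labels] + 1.5 * texture, 2.5, 30.0), 0.0)

    grid_kw = dict(
        origin=(0.0, nrow * params.pixel_size),
        pixel_size=params.pixel_size,
        crs="synthetic-planar",
    )
    return LandscapeTruth(
        tree_mask=RasterGrid(mask, nodata=255, **grid_kw),
        tree_height=RasterGrid(heights, **grid_kw),
        terrain=RasterGrid(terrain, **grid_kw),
        division_polygons=_division_boxes(params),
        forest_exclusion=forest_polys,
        seed=params.seed,
    )


# ---------------------------------------------------------------------------
# renderers

def _ndvi_to_bands(
    ndvi: np.ndarray, brightness: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Invert NDVI to (red, nir) given total brightness red + nir."""
    red = brightness * (1.0 - ndvi) / 2.0
    nir = brightness * (1.0 + ndvi) / 2.0
    return red, nir


def render_optical_series(truth: LandscapeTruth, params: SceneParams) -> SceneCollection:
    """Dry-season red/NIR series whose NDVI separates trees from the rest.

    Noiseless tree pixels reach an NDVI in (0.35, 0.85) on their greenest
    date; non-tree pixels (water, settlement, fallow cropland) stay below
    0.3 on every date.  Optional cloud occlusion pulls whole blobs of a date
    toward NDVI 0, to be discarded by greenest compositing downstream.
    """
    params.validate()
    rng = np.random.default_rng([int(params.seed), 1])
    dates = list(params.optical_dates)
    n_dates = len(dates)
    tree = truth.tree_mask.data > 0
    shape = truth.tree_mask.shape

    # non-tree cover classes from a smooth field: water / settlement / fallow
    zone = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=12.0)
    z = (zone - zone.mean()) / (zone.std() or 1.0)
    base_ndvi = np.where(z < -1.2, rng.uniform(-0.30, 0.00, shape),      # water
               np.where(z > 1.2, rng.uniform(0.02, 0.15, shape),         # settlement
                        rng.uniform(0.05, 0.28, shape)))                 # fallow field
    peak = rng.uniform(0.45, 0.62, shape)                                # tree greenness
    greenest = rng.integers(0, n_dates, size=shape)                      # per-pixel argmax date
    brightness = np.where(tree, rng.uniform(0.60, 0.90, shape), rng.uniform(0.45, 0.85, shape))

    arrays: dict[str, dict[str, np.ndarray]] = {}
    for d_idx, date in enumerate(dates):
        off_peak = 0.08 * np.abs(d_idx - greenest)
        ndvi = np.where(tree, peak - off_peak, np.clip(base_ndvi + rng.normal(0, 0.01, shape), -0.9, 0.295))
        if params.cloud_fraction > 0:
            cloud_field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=10.0)
            thresh = np.quantile(cloud_field, 1.0 - params.cloud_fraction)
            ndvi = np.where(cloud_field > thresh, rng.uniform(-0.05, 0.05, shape), ndvi)
        red, nir = _ndvi_to_bands(ndvi, brightness)
        if params.optical_noise_sd > 0:
            red = red + rng.normal(0, params.optical_noise_sd, shape)
            nir = nir + rng.normal(0, params.optical_noise_sd, shape)
        arrays[date] = {
            "red": np.clip(red, 0.0, 1.0),
            "nir": np.clip(nir, 0.0, 1.0),
        }
    return SceneCollection.from_arrays(dates, ["red", "nir"], arrays, like=truth.terrain)


def render_sar_series(
    truth: LandscapeTruth, params: SceneParams
) -> tuple[SceneCollection, SceneCollection]:
    """Ascending and descending VH/VV backscatter series in dB.

    Trees sit inside the volumetric-scattering windows (temporal VH mean in
    [-14, -9] dB, VV in [-8, -2] dB); water, settlement and open fields each
    violate at least one window.  The descending stack carries full-height
    vertical scan-line stripes at -30 dB covering the configured fraction of
    pixels; the ascending stack has none, so it can donate fill values.
    """
    params.validate()
    rng = np.random.default_rng([int(params.seed), 2])
    dates = list(params.sar_dates)
    shape = truth.tree_mask.shape
    nrow, ncol = shape
    tree = truth.tree_mask.data > 0

    zone = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=12.0)
    z = (zone - zone.mean()) / (zone.std() or 1.0)
    # per-pixel temporal-mean targets (dB); each class breaks a window
    vh_bg = np.where(z < -1.2, rng.uniform(-24.0, -18.0, shape),   # water: VH too low
            np.where(z > 1.2, rng.uniform(-7.5, -4.0, shape),      # settlement: VH too high
                     rng.uniform(-20.0, -15.5, shape)))            # field: VH too low
    vv_bg = np.where(z < -1.2, rng.uniform(-16.0, -11.5, shape),
            np.where(z > 1.2, rng.uniform(-1.5, 1.0, shape),
                     rng.uniform(-12.0, -9.0, shape)))
    vh_mean = np.where(tree, rng.uniform(-12.7, -10.3, shape), vh_bg)
    vv_mean = np.where(tree, rng.uniform(-6.7, -3.3, shape), vv_bg)

    # scan-line stripes: vertical, full height, 1-3 px wide, exact column budget
    stripe_cols = np.zeros(ncol, dtype=bool)
    budget = int(round(params.scanline_gap_fraction * ncol))
    while stripe_cols.sum() < budget:
        width = min(int(rng.integers(1, 4)), budget - int(stripe_cols.sum()))
        start = int(rng.integers(0, ncol - width + 1))
        stripe_cols[start : start + width] = True

    def _stack(mean_db: np.ndarray, striped: bool) -> dict[str, np.ndarray]:
        per_date = {}
        for date in dates:
            img = mean_db.copy()
            if params.sar_speckle_sd_db > 0:
                img = img + rng.normal(0, params.sar_speckle_sd_db, shape)
            if striped:
                img[:, stripe_cols] = SCANLINE_DB
            per_date[date] = img
        return per_date

    like = truth.terrain
    asc_vh, asc_vv = _stack(vh_mean, False), _stack(vv_mean, False)
    desc_vh, desc_vv = _stack(vh_mean, True), _stack(vv_mean, True)
    asc = SceneCollection.from_arrays(
        dates, ["VH", "VV"],
        {d: {"VH": asc_vh[d], "VV": asc_vv[d]} for d in dates}, like=like,
    )
    desc = SceneCollection.from_arrays(
        dates, ["VH", "VV"],
        {d: {"VH": desc_vh[d], "VV": desc_vv[d]} for d in dates}, like=like,
    )
    return asc, desc


def render_dsm(
    truth: LandscapeTruth, params: SceneParams
) -> tuple[RasterGrid, RasterGrid]:
    """Surface model pair: the working DSM and an independent reference.

    Over tree pixels ``dsm = terrain + slope * height + intercept + noise``
    (the slope/intercept emulate radar penetration into the canopy); over
    bare pixels ``dsm = terrain + noise``.  The reference surface applies its
    own bias and noise, standing in for a stereo-photogrammetric canopy
    surface used for calibration.
    """
    params.validate()
    rng = np.random.default_rng([int(params.seed), 3])
    tree = truth.tree_mask.data > 0
    terrain = truth.terrain.data
    h = truth.tree_height.data

    def _surface(bias: tuple[float, float], noise_sd: float) -> np.ndarray:
        slope, intercept = bias
        canopy = np.where(tree, slope * h + intercept, 0.0)
        out = terrain + canopy
        if noise_sd > 0:
            out = out + rng.normal(0, noise_sd, terrain.shape)
        return out

    dsm = truth.terrain.with_data(_surface(params.dsm_canopy_bias, params.dsm_noise_sd))
    ref = truth.terrain.with_data(_surface(params.reference_bias, params.reference_noise_sd))
    return dsm, ref


def sample_gcps(
    truth: LandscapeTruth, n: int, holdout: int, seed: int
) -> tuple[GCPSet, GCPSet]:
    """Sample disjoint fitting and holdout bare-ground control points.

    Points land only on non-tree pixels and read their elevation from the
    noiseless terrain field, at pixel centers.
    """
    if n < 1 or holdout < 0:
        raise ValueError("need n >= 1 and holdout >= 0")
    bare_rows, bare_cols = np.nonzero(truth.tree_mask.data == 0)
    if n + holdout > bare_rows.size:
        raise ValueError(
            f"requested {n + holdout} points but only {bare_rows.size} bare pixels exist"
        )
    rng = np.random.default_rng([int(seed), 4])
    pick = rng.permutation(bare_rows.size)[: n + holdout]
    rows, cols = bare_rows[pick], bare_cols[pick]
    x0, y0 = truth.terrain.origin
    px = truth.terrain.pixel_size
    xs = x0 + (cols + 0.5) * px
    ys = y0 - (rows + 0.5) * px
    zs = truth.terrain.data[rows, cols]
    fit = GCPSet(x=xs[:n], y=ys[:n], elevation=zs[:n])
    hold = GCPSet(x=xs[n:], y=ys[n:], elevation=zs[n:])
    return fit, hold
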