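"""Area accounting, map comparison and stratified accuracy assessment.

Covers the reporting layer of a national tree-extent analysis: per-division
areas and cover percentages, conversions of canopy-cover products to extent
masks for map-to-map comparison, per-capita figures, and the good-practice
stratified estimators for overall accuracy and unbiased class areas with
95% confidence intervals.

Stratified estimators.  With strata ``h`` (e.g. division x mapped class),
stratum weight ``W_h`` (mapped-area proportion), ``n_h`` validation points
of which ``n_hj`` carry reference class ``j``::

    p_hj   = n_hj / n_h
    p_.j   = sum_h W_h p_hj                      (share of ref class j)
    A_j    = A_total * p_.j                      (unbiased area estimate)
    SE_.j  = sqrt( sum_h W_h^2 p_hj (1-p_hj) / (n_h - 1) )
    CI95_j = 1.96 * SE_.j * A_total

Overall accuracy is ``sum_h W_h p_h,m(h)`` where ``m(h)`` is the stratum's
mapped class.  With a single stratum these collapse to the simple binomial
proportion and its normal-approximation interval.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from shapely.geometry.base import BaseGeometry

from .grid import RasterGrid
from .vector import rasterize_polygons

__all__ = [
    "AccuracyReport",
    "division_summary",
    "summarize_division_areas",
    "cover_to_extent",
    "compare_maps",
    "per_capita",
    "validate_points",
    "stratified_accuracy",
    "stratified_sample_points",
    "stratum_mapped_areas",
]

Z_95 = 1.96


# ---------------------------------------------------------------------------
# per-division area accounting

def division_summary(
    mask: RasterGrid,
    divisions: Mapping[str, BaseGeometry],
    ci_ha: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Tree area, cover percentage and optional 95% CI per division.

    Division areas come from rasterized pixel counts, so the national total
    equals the sum of divisions exactly.  Overlapping division polygons are
    rejected.
    """
    from .vector import polygon_mask

    cover = np.zeros(mask.shape, dtype=np.int8)
    for geom in divisions.values():
        cover += polygon_mask(mask, [geom]).astype(np.int8)
    if (cover > 1).any():
        raise ValueError("division polygons overlap")
    zones, names = rasterize_polygons(mask, divisions)
    pa = mask.pixel_area_ha
    tree = mask.data == 1
    rows = []
    for zid, name in enumerate(names, start=1):
        in_zone = zones == zid
        tof_ha = float(tree[in_zone].sum()) * pa
        div_ha = float(in_zone.sum()) * pa
        rows.append(
            {
                "division": name,
                "tof_ha": tof_ha,
                "division_area_ha": div_ha,
                "pct_tof": 100.0 * tof_ha / div_ha if div_ha else 0.0,
                "ci95_ha": float(ci_ha[name]) if ci_ha else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    total = {
        "division": "Total",
        "tof_ha": df["tof_ha"].sum(),
        "division_area_ha": df["division_area_ha"].sum(),
        "ci95_ha": np.nan,
    }
    total["pct_tof"] = (
        100.0 * total["tof_ha"] / total["division_area_ha"]
        if total["division_area_ha"]
        else 0.0
    )
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)


def summarize_division_areas(
    tof_ha: Mapping[str, float],
    division_area_ha: Mapping[str, float],
    ci_ha: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Division summary arithmetic from already-tabulated areas.

    Used when the mapped areas per division are inputs (e.g. published
    national figures) rather than a raster in hand.
    """
    if set(tof_ha) != set(division_area_ha):
        raise ValueError("tof_ha and division_area_ha must cover the same divisions")
    rows = [
        {
            "division": name,
            "tof_ha": float(tof_ha[name]),
            "division_area_ha": float(division_area_ha[name]),
            "pct_tof": 100.0 * tof_ha[name] / division_area_ha[name],
            "ci95_ha": float(ci_ha[name]) if ci_ha else np.nan,
        }
        for name in tof_ha
    ]
    df = pd.DataFrame(rows)
    tot_tof = df["tof_ha"].sum()
    tot_div = df["division_area_ha"].sum()
    total = {
        "division": "Total",
        "tof_ha": tot_tof,
        "division_area_ha": tot_div,
        "pct_tof": 100.0 * tot_tof / tot_div,
        "ci95_ha": np.nan,
    }
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)


def cover_to_extent(percent_cover: RasterGrid, threshold_pct: float = 0.0) -> RasterGrid:
    """Convert a canopy-cover-percentage raster to a binary extent mask.

    A pixel becomes tree extent iff its cover strictly exceeds the
    threshold (0% by default, so any cover at all counts as extent).
    """
    valid = percent_cover.valid_mask()
    vals = percent_cover.data.astype(float)
    if ((vals[valid] < 0) | (vals[valid] > 100)).any():
        raise ValueError("percent cover must lie in [0, 100]")
    out = np.where(valid & (vals > threshold_pct), 1, 0).astype(np.uint8)
    out[~valid] = 255
    return percent_cover.with_data(out, nodata=255)


def compare_maps(
    summary_a: Mapping[str, float], summary_b: Mapping[str, float]
) -> pd.DataFrame:
    """Per-division area differences between two maps (a minus b).

    ``pct_diff`` uses map b as the denominator.  A national row sums both
    maps before differencing.
    """
    if set(summary_a) != set(summary_b):
        raise ValueError("maps cover different division sets")
    rows = [
        {
            "division": name,
            "area_a_ha": float(summary_a[name]),
            "area_b_ha": float(summary_b[name]),
            "diff_ha": float(summary_a[name]) - float(summary_b[name]),
            "pct_diff": 100.0 * (summary_a[name] - summary_b[name]) / summary_b[name],
        }
        for name in summary_a
    ]
    a_tot = sum(summary_a.values())
    b_tot = sum(summary_b.values())
    rows.append(
        {
            "division": "Total",
            "area_a_ha": a_tot,
            "area_b_ha": b_tot,
            "diff_ha": a_tot - b_tot,
            "pct_diff": 100.0 * (a_tot - b_tot) / b_tot,
        }
    )
    return pd.DataFrame(rows)


def per_capita(total_ha: float, population: int) -> float:
    """Tree area per person in hectares, reported to 3 decimals."""
    if population <= 0:
        raise ValueError("population must be positive")
    return round(total_ha / population, 3)


# ---------------------------------------------------------------------------
# stratified accuracy assessment

@dataclass
class AccuracyReport:
    """Stratified accuracy and area estimates for a binary extent map."""

    classes: list[int]
    strata: list[str]
    weights: dict[str, float]
    n_points: dict[str, int]
    overall_accuracy: float
    users_accuracy: dict[int, float]
    producers_accuracy: dict[int, float]
    area_ha: dict[int, float]
    se_area_ha: dict[int, float]
    ci95_ha: dict[int, float]
    total_area_ha: float
    n_points_excluded: int = 0
    confusion: pd.DataFrame | None = field(default=None, repr=False)

    def to_json(self, path) -> None:
        doc = {
            "overall_accuracy": self.overall_accuracy,
            "users_accuracy": {str(k): v for k, v in self.users_accuracy.items()},
            "producers_accuracy": {str(k): v for k, v in self.producers_accuracy.items()},
            "area_ha": {str(k): v for k, v in self.area_ha.items()},
            "se_area_ha": {str(k): v for k, v in self.se_area_ha.items()},
            "ci95_ha": {str(k): v for k, v in self.ci95_ha.items()},
            "total_area_ha": self.total_area_ha,
            "strata": self.strata,
            "weights": self.weights,
            "n_points": self.n_points,
            "n_points_excluded": self.n_points_excluded,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)


def stratified_sample_points(
    mask: RasterGrid,
    divisions: Mapping[str, BaseGeometry],
    points_per_class: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a stratified validation sample from a mapped extent raster.

    For every division and each mapped class (tree / non-tree) the sampler
    draws up to ``points_per_class`` pixel centers without replacement,
    mirroring a two-class national validation campaign.  Strata are
    ``"<division>/<class>"``.
    """
    rng = np.random.default_rng([int(seed), 5])
    zones, names = rasterize_polygons(mask, divisions)
    x0, y0 = mask.origin
    px = mask.pixel_size
    records = []
    for zid, name in enumerate(names, start=1):
        for cls in (0, 1):
            rows, cols = np.nonzero((zones == zid) & (mask.data == cls))
            if rows.size == 0:
                continue
            take = min(points_per_class, rows.size)
            pick = rng.choice(rows.size, size=take, replace=False)
            for r, c in zip(rows[pick], cols[pick]):
                records.append(
                    {
                        "x": x0 + (c + 0.5) * px,
                        "y": y0 - (r + 0.5) * px,
                        "stratum": f"{name}/{cls}",
                        "map_label": cls,
                    }
                )
    return pd.DataFrame(records)


def validate_points(
    mask: RasterGrid, points: pd.DataFrame, buffer_m: float = 10.0
) -> tuple[pd.DataFrame, int]:
    """Confusion counts per stratum from labeled validation points.

    The mapped label is the mask value at each point, with a geolocation
    allowance: if the mask disagrees with the reference label but any pixel
    whose center lies within ``buffer_m`` of the point carries the reference
    label, the point counts as agreement (it lands on the diagonal cell of
    its own stratum, so strata keep a single mapped class).  Points outside
    the raster (or on nodata) are excluded and counted.  Returns a tidy
    count table with columns ``stratum, map_label, ref_label, n`` and the
    number excluded.
    """
    required = {"x", "y", "ref_label", "stratum"}
    if not required.issubset(points.columns):
        raise ValueError(f"points need columns {sorted(required)}")
    nrow, ncol = mask.shape
    px = mask.pixel_size
    reach = int(np.ceil(buffer_m / px)) if buffer_m > 0 else 0
    tallies: dict[tuple[str, int, int], int] = {}
    n_excluded = 0
    rows, cols = mask.xy_to_rowcol(points["x"].to_numpy(), points["y"].to_numpy())
    data = mask.data
    valid = mask.valid_mask()
    for i, (r, c) in enumerate(zip(rows, cols)):
        if not (0 <= r < nrow and 0 <= c < ncol) or not valid[r, c]:
            n_excluded += 1
            continue
        ref = int(points["ref_label"].iloc[i])
        mapped = int(data[r, c])
        if mapped != ref and reach > 0:
            r0, r1 = max(0, r - reach), min(nrow, r + reach + 1)
            c0, c1 = max(0, c - reach), min(ncol, c + reach + 1)
            window = data[r0:r1, c0:c1]
            wr, wc = np.indices(window.shape)
            dist = np.hypot(wr + r0 - r, wc + c0 - c) * px
            if ((window == ref) & (dist <= buffer_m)).any():
                ref = mapped  # geolocation allowance: agreement within buffer
        key = (str(points["stratum"].iloc[i]), mapped, ref)
        tallies[key] = tallies.get(key, 0) + 1
    counts = pd.DataFrame(
        [
            {"stratum": s, "map_label": m, "ref_label": rl, "n": n}
            for (s, m, rl), n in sorted(tallies.items())
        ]
    )
    return counts, n_excluded


def stratum_mapped_areas(
    mask: RasterGrid, divisions: Mapping[str, BaseGeometry]
) -> dict[str, float]:
    """Mapped area (ha) of every division x class stratum."""
    zones, names = rasterize_polygons(mask, divisions)
    pa = mask.pixel_area_ha
    out = {}
    for zid, name in enumerate(names, start=1):
        for cls in (0, 1):
            out[f"{name}/{cls}"] = float(((zones == zid) & (mask.data == cls)).sum()) * pa
    return out


def stratified_accuracy(
    counts: pd.DataFrame,
    mapped_areas: Mapping[str, float],
    *,
    n_points_excluded: int = 0,
) -> AccuracyReport:
    """Good-practice accuracy and area estimators from stratified counts.

    ``counts`` is the tidy table from :func:`validate_points`; each stratum
    must carry a single mapped class (its own map stratum) and at least one
    point.  ``mapped_areas`` gives the mapped area in hectares per stratum;
    weights are their proportions of the total.
    """
    if counts.empty:
        raise ValueError("no validation counts supplied")
    strata = sorted(s for s in counts["stratum"].unique())
    for s in strata:
        if s not in mapped_areas:
            raise ValueError(f"no mapped area supplied for stratum {s!r}")
    a_total = float(sum(mapped_areas.values()))
    if a_total <= 0:
        raise ValueError("total mapped area must be positive")
    weights = {s: mapped_areas[s] / a_total for s in mapped_areas}
    # strata with mapped area but no points are only legal when empty of area
    for s, a in mapped_areas.items():
        if a > 0 and s not in strata:
            raise ValueError(f"stratum {s!r} has mapped area but no validation points")

    classes = sorted(
        set(counts["map_label"].unique()) | set(counts["ref_label"].unique())
    )
    n_h = counts.groupby("stratum")["n"].sum().to_dict()
    map_class_of = {}
    for s in strata:
        mls = counts.loc[counts["stratum"] == s, "map_label"].unique()
        if len(mls) != 1:
            raise ValueError(f"stratum {s!r} mixes mapped classes {sorted(mls)}")
        map_class_of[s] = int(mls[0])

    # reference-class proportions per stratum
    p_hj = {
        (s, j): float(
            counts.loc[
                (counts["stratum"] == s) & (counts["ref_label"] == j), "n"
            ].sum()
        )
        / n_h[s]
        for s in strata
        for j in classes
    }

    p_dot_j = {j: sum(weights[s] * p_hj[(s, j)] for s in strata) for j in classes}
    overall = sum(weights[s] * p_hj[(s, map_class_of[s])] for s in strata)

    se = {}
    for j in classes:
        var = 0.0
        for s in strata:
            p = p_hj[(s, j)]
            denom = max(n_h[s] - 1, 1)
            var += weights[s] ** 2 * p * (1 - p) / denom
        se[j] = float(np.sqrt(var))

    users = {}
    producers = {}
    for j in classes:
        w_map = sum(weights[s] for s in strata if map_class_of[s] == j)
        correct = sum(
            weights[s] * p_hj[(s, j)] for s in strata if map_class_of[s] == j
        )
        users[j] = correct / w_map if w_map > 0 else np.nan
        producers[j] = correct / p_dot_j[j] if p_dot_j[j] > 0 else np.nan

    return AccuracyReport(
        classes=[int(c) for c in classes],
        strata=strata,
        weights={s: float(weights[s]) for s in strata},
        n_points={s: int(n_h[s]) for s in strata},
        overall_accuracy=float(overall),
        users_accuracy={int(j): float(users[j]) for j in classes},
        producers_accuracy={int(j): float(producers[j]) for j in classes},
        area_ha={int(j): float(a_total * p_dot_j[j]) for j in classes},
        se_area_ha={int(j): float(a_total * se[j]) for j in classes},
        ci95_ha={int(j): float(Z_95 * a_total * se[j]) for j in classes},
        total_area_ha=a_total,
        n_points_excluded=n_points_excluded,
        confusion=counts.copy(),
    )
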