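import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from tofscape import bangladesh as bd
from tofscape.accounting import (
    compare_maps,
    cover_to_extent,
    division_summary,
    per_capita,
    stratified_accuracy,
    stratified_sample_points,
    stratum_mapped_areas,
    summarize_division_areas,
    validate_points,
)


class TestDivisionSummary:
    def test_published_division_arithmetic(self):
        df = summarize_division_areas(bd.TOF_AREA_HA, bd.DIVISION_AREA_HA, bd.TOF_CI95_HA)
        by = df.set_index("division")
        assert round(by.loc["Barisal", "pct_tof"], 1) == 22.8
        assert round(by.loc["Total", "pct_tof"], 1) == 15.1
        assert by.loc["Total", "tof_ha"] == 2_233_578

    def test_raster_areas_conserve_exactly(self, grid_factory):
        data = np.zeros((20, 20), dtype=np.uint8)
        data[2:8, 3:9] = 1
        data[12:18, 12:19] = 1
        mask = grid_factory(data, nodata=255)
        divisions = {"west": box(0, 0, 100, 200), "east": box(100, 0, 200, 200)}
        df = division_summary(mask, divisions).set_index("division")
        assert df.loc["Total", "tof_ha"] == pytest.approx(
            df.loc[["west", "east"], "tof_ha"].sum()
        )
        assert df.loc["Total", "tof_ha"] == pytest.approx(data.sum() * 0.01)

    def test_empty_mask_gives_zeros(self, grid_factory):
        mask = grid_factory(np.zeros((10, 10), dtype=np.uint8), nodata=255)
        df = division_summary(mask, {"all": box(0, 0, 100, 100)})
        assert (df["tof_ha"] == 0).all()
        assert (df["pct_tof"] == 0).all()

    def test_overlapping_divisions_rejected(self, grid_factory):
        mask = grid_factory(np.zeros((10, 10), dtype=np.uint8), nodata=255)
        with pytest.raises(ValueError, match="overlap"):
            division_summary(mask, {"a": box(0, 0, 80, 100), "b": box(40, 0, 100, 100)})


class TestCoverToExtent:
    def test_zero_cover_excluded_any_cover_included(self, grid_factory):
        cover = grid_factory(np.array([[0.0, 0.5, 37.0]]))
        out = cover_to_extent(cover)
        np.testing.assert_array_equal(out.data, [[0, 1, 1]])

    def test_nodata_propagates(self, grid_factory):
        cover = grid_factory(np.array([[np.nan]]), nodata=float("nan"))
        assert cover_to_extent(cover).data[0, 0] == 255

    def test_custom_threshold(self, grid_factory):
        cover = grid_factory(np.array([[10.0, 10.1]]))
        np.testing.assert_array_equal(cover_to_extent(cover, 10.0).data, [[0, 1]])


class TestCompareMaps:
    def test_published_cover_map_differences(self):
        df = compare_maps(bd.TOF_AREA_HA, bd.COVER_MAP_AREA_HA).set_index("division")
        assert df.loc["Dhaka", "diff_ha"] == 286_862
        assert df.drop("Total")["diff_ha"].min() == 38_939  # smallest discrepancy
        assert (df.drop("Total")["diff_ha"] > 0).all()  # more extent in every division

    def test_published_fnf_differences(self):
        df = compare_maps(bd.TOF_AREA_HA, bd.FNF_AREA_HA).set_index("division")
        assert df.loc["Rajshahi", "diff_ha"] == 20_956
        assert df.loc["Sylhet", "diff_ha"] == 29_380
        # five of eight divisions show more forest in the radar FNF product
        assert (df.drop("Total")["diff_ha"] < 0).sum() == 5

    def test_identical_maps_give_zero(self):
        df = compare_maps(bd.TOF_AREA_HA, bd.TOF_AREA_HA)
        assert (df["diff_ha"] == 0).all()

    def test_division_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_maps({"a": 1.0}, {"b": 1.0})


class TestPerCapita:
    def test_national_figure(self):
        total = sum(bd.TOF_AREA_HA.values())
        assert per_capita(total, bd.POPULATION) == 0.014

    @pytest.mark.parametrize("ha,pop,expected", [(0, 10, 0.0), (1, 1, 1.0)])
    def test_edges(self, ha, pop, expected):
        assert per_capita(ha, pop) == expected

    def test_zero_population_rejected(self):
        with pytest.raises(ValueError):
            per_capita(1.0, 0)


class TestValidatePoints:
    def _mask(self, grid_factory):
        data = np.zeros((10, 10), dtype=np.uint8)
        data[4, 4] = 1
        return grid_factory(data, nodata=255)

    def test_direct_hit_buffer_zero(self, grid_factory):
        mask = self._mask(grid_factory)
        pts = pd.DataFrame({"x": [45.0], "y": [55.0], "ref_label": [1], "stratum": ["s"]})
        counts, n_excl = validate_points(mask, pts, buffer_m=0.0)
        assert n_excl == 0
        assert counts.iloc[0]["map_label"] == 1 and counts.iloc[0]["ref_label"] == 1

    def test_one_pixel_offset_rescued_by_10m_buffer(self, grid_factory):
        mask = self._mask(grid_factory)
        pts = pd.DataFrame({"x": [55.0], "y": [55.0], "ref_label": [1], "stratum": ["s"]})
        hit, _ = validate_points(mask, pts, buffer_m=10.0)
        # neighbour pixel carries the label, so the point counts as agreement
        assert hit.iloc[0]["map_label"] == hit.iloc[0]["ref_label"]
        miss, _ = validate_points(mask, pts, buffer_m=0.0)
        assert miss.iloc[0]["map_label"] != miss.iloc[0]["ref_label"]

    def test_out_of_raster_points_excluded_and_counted(self, grid_factory):
        mask = self._mask(grid_factory)
        pts = pd.DataFrame({"x": [-5.0], "y": [55.0], "ref_label": [1], "stratum": ["s"]})
        counts, n_excl = validate_points(mask, pts, buffer_m=0.0)
        assert n_excl == 1 and counts.empty


class TestStratifiedAccuracy:
    def test_single_stratum_collapses_to_simple_proportion(self):
        counts = pd.DataFrame(
            [
                {"stratum": "s", "map_label": 1, "ref_label": 1, "n": 90},
                {"stratum": "s", "map_label": 1, "ref_label": 0, "n": 10},
            ]
        )
        report = stratified_accuracy(counts, {"s": 1000.0})
        assert report.overall_accuracy == pytest.approx(0.90)

    def test_two_equal_strata_weighted_mean(self):
        counts = pd.DataFrame(
            [
                {"stratum": "a", "map_label": 1, "ref_label": 1, "n": 80},
                {"stratum": "a", "map_label": 1, "ref_label": 0, "n": 20},
                {"stratum": "b", "map_label": 0, "ref_label": 0, "n": 100},
            ]
        )
        report = stratified_accuracy(counts, {"a": 500.0, "b": 500.0})
        assert report.overall_accuracy == pytest.approx(0.9)

    def test_perfect_agreement_gives_zero_ci(self):
        counts = pd.DataFrame(
            [
                {"stratum": "a", "map_label": 1, "ref_label": 1, "n": 50},
                {"stratum": "b", "map_label": 0, "ref_label": 0, "n": 50},
            ]
        )
        report = stratified_accuracy(counts, {"a": 300.0, "b": 700.0})
        assert report.overall_accuracy == 1.0
        assert report.ci95_ha[1] == 0.0
        assert report.area_ha[1] == pytest.approx(300.0)

    def test_single_stratum_matches_binomial_normal_ci(self):
        n, k = 200, 170
        counts = pd.DataFrame(
            [
                {"stratum": "s", "map_label": 1, "ref_label": 1, "n": k},
                {"stratum": "s", "map_label": 1, "ref_label": 0, "n": n - k},
            ]
        )
        a_total = 5000.0
        report = stratified_accuracy(counts, {"s": a_total})
        p = k / n
        se = np.sqrt(p * (1 - p) / (n - 1))
        assert report.ci95_ha[1] == pytest.approx(1.96 * se * a_total, rel=1e-12)

    def test_ci_matches_stratified_bootstrap(self):
        # two-class, two-stratum fixture; 10,000-rep bootstrap oracle
        rng = np.random.default_rng(17)
        counts = pd.DataFrame(
            [
                {"stratum": "tree", "map_label": 1, "ref_label": 1, "n": 85},
                {"stratum": "tree", "map_label": 1, "ref_label": 0, "n": 15},
                {"stratum": "bare", "map_label": 0, "ref_label": 1, "n": 12},
                {"stratum": "bare", "map_label": 0, "ref_label": 0, "n": 138},
            ]
        )
        areas = {"tree": 2000.0, "bare": 8000.0}
        report = stratified_accuracy(counts, areas)
        w = {s: areas[s] / 10000.0 for s in areas}
        reps = 10_000
        boot_tree = w["tree"] * rng.binomial(100, 0.85, reps) / 100 + w["bare"] * rng.binomial(
            150, 12 / 150, reps
        ) / 150
        boot_ci = 1.96 * boot_tree.std(ddof=1) * 10000.0
        assert report.ci95_ha[1] == pytest.approx(boot_ci, rel=0.10)

    def test_empty_stratum_rejected(self):
        counts = pd.DataFrame(
            [{"stratum": "a", "map_label": 1, "ref_label": 1, "n": 10}]
        )
        with pytest.raises(ValueError):
            stratified_accuracy(counts, {"a": 100.0, "b": 900.0})


class TestStratifiedSampling:
    def test_sample_respects_strata(self, grid_factory):
        rng = np.random.default_rng(0)
        data = (rng.random((64, 64)) < 0.3).astype(np.uint8)
        mask = grid_factory(data, nodata=255)
        divisions = {"w": box(0, 0, 320, 640), "e": box(320, 0, 640, 640)}
        pts = stratified_sample_points(mask, divisions, points_per_class=30, seed=1)
        assert set(pts["stratum"]) == {"w/0", "w/1", "e/0", "e/1"}
        rows, cols = mask.xy_to_rowcol(pts["x"].to_numpy(), pts["y"].to_numpy())
        np.testing.assert_array_equal(mask.data[rows, cols], pts["map_label"])

    def test_weights_from_mapped_areas_sum_to_one(self, grid_factory):
        rng = np.random.default_rng(0)
        data = (rng.random((64, 64)) < 0.3).astype(np.uint8)
        mask = grid_factory(data, nodata=255)
        divisions = {"w": box(0, 0, 320, 640), "e": box(320, 0, 640, 640)}
        areas = stratum_mapped_areas(mask, divisions)
        assert sum(areas.values()) == pytest.approx(64 * 64 * 0.01)
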