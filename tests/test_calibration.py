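import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from tofscape.calibration import (
    CalibrationModel,
    aggregate_plots,
    apply_calibration,
    exclude_outliers,
    fit_calibration,
    height_summary,
)


def _model(slope=1.0, intercept=0.0, **kw):
    defaults = dict(mae_before=0.0, mae_after=0.0, n_plots_used=10, n_outliers_excluded=0)
    defaults.update(kw)
    return CalibrationModel(slope=slope, intercept=intercept, **defaults)


class TestAggregatePlots:
    def test_uniform_fields_give_uniform_plot_means(self, grid_factory):
        chm = grid_factory(np.full((20, 20), 8.0))
        ref = grid_factory(np.full((20, 20), 10.0))
        mask = grid_factory(np.ones((20, 20), dtype=np.uint8), nodata=255)
        plots = aggregate_plots(chm, ref, mask)
        assert len(plots) == 4  # 2x2 complete 10x10 tiles
        assert (plots["mean_raw_height"] == 8.0).all()
        assert (plots["mean_reference_height"] == 10.0).all()

    def test_empty_tile_absent(self, grid_factory):
        chm = grid_factory(np.full((20, 20), 5.0))
        mask_data = np.zeros((20, 20), dtype=np.uint8)
        mask_data[:10, :10] = 1  # only the top-left tile has trees
        mask = grid_factory(mask_data, nodata=255)
        plots = aggregate_plots(chm, chm, mask)
        assert len(plots) == 1

    def test_unmasked_pixels_never_contribute(self, grid_factory):
        data = np.full((10, 10), 99.0)
        mask_data = np.zeros((10, 10), dtype=np.uint8)
        mask_data[::2, ::2] = 1  # checkerboard-ish
        data[mask_data == 1] = 4.0
        chm = grid_factory(data)
        mask = grid_factory(mask_data, nodata=255)
        plots = aggregate_plots(chm, chm, mask)
        assert plots["mean_raw_height"].iloc[0] == pytest.approx(4.0)

    def test_no_complete_tile_rejected(self, grid_factory):
        small = grid_factory(np.zeros((5, 5)))
        mask = grid_factory(np.ones((5, 5), dtype=np.uint8), nodata=255)
        with pytest.raises(ValueError):
            aggregate_plots(small, small, mask)


class TestExcludeOutliers:
    def test_identical_surfaces_remove_nothing(self):
        plots = pd.DataFrame(
            {"mean_raw_height": np.arange(10.0), "mean_reference_height": np.arange(10.0)}
        )
        kept, n = exclude_outliers(plots)
        assert n == 0 and len(kept) == 10

    def test_single_gross_outlier_removed(self):
        raw = np.full(1001, 5.0)
        ref = raw + 1.0
        ref[500] = raw[500] + 50.0  # one 50 m disagreement among 1 m ones
        plots = pd.DataFrame({"mean_raw_height": raw, "mean_reference_height": ref})
        kept, n = exclude_outliers(plots)
        assert n == 1
        assert len(kept) == 1000
        assert (kept["mean_reference_height"] - kept["mean_raw_height"]).max() == 1.0


class TestFitCalibration:
    def test_identity_data_gives_identity_model(self):
        rng = np.random.default_rng(0)
        h = rng.uniform(2, 20, 50)
        plots = pd.DataFrame({"mean_raw_height": h, "mean_reference_height": h})
        m = fit_calibration(plots)
        assert m.slope == pytest.approx(1.0)
        assert m.intercept == pytest.approx(0.0, abs=1e-9)
        assert m.mae_before == pytest.approx(0.0, abs=1e-12)

    def test_exact_line_recovered(self):
        rng = np.random.default_rng(1)
        h = rng.uniform(2, 20, 50)
        plots = pd.DataFrame({"mean_raw_height": h, "mean_reference_height": 2 * h + 1})
        m = fit_calibration(plots)
        assert m.slope == pytest.approx(2.0)
        assert m.intercept == pytest.approx(1.0)
        assert m.mae_after == pytest.approx(0.0, abs=1e-9)

    def test_mae_never_increases(self):
        rng = np.random.default_rng(2)
        h = rng.uniform(2, 20, 200)
        ref = 0.9 * h + 1.5 + rng.normal(0, 0.4, 200)
        plots = pd.DataFrame({"mean_raw_height": h, "mean_reference_height": ref})
        m = fit_calibration(plots)
        assert m.mae_after <= m.mae_before

    def test_degenerate_variance_rejected(self):
        plots = pd.DataFrame(
            {"mean_raw_height": [5.0] * 10, "mean_reference_height": np.arange(10.0)}
        )
        with pytest.raises(ValueError):
            fit_calibration(plots)


class TestApplyCalibration:
    def test_nonpositive_raw_removed(self, grid_factory):
        chm = grid_factory(np.array([[0.0, -2.0, 10.0]]), nodata=float("nan"))
        out = apply_calibration(chm, _model())
        assert np.isnan(out.data[0, 0]) and np.isnan(out.data[0, 1])
        assert out.data[0, 2] == pytest.approx(10.0)

    def test_minimum_height_rule(self, grid_factory):
        chm = grid_factory(np.array([[2.0, 3.0]]), nodata=float("nan"))
        out = apply_calibration(chm, _model())  # identity transform
        assert np.isnan(out.data[0, 0])  # 2.0 m does not exceed 2.19 m
        assert out.data[0, 1] == pytest.approx(3.0)

    def test_uniform_division_unchanged_by_cap(self, grid_factory):
        chm = grid_factory(np.full((10, 10), 10.0), nodata=float("nan"))
        zones = {"only": box(0, 0, 100, 100)}
        out = apply_calibration(chm, _model(), zones)
        np.testing.assert_allclose(out.data, 10.0)

    def test_per_division_percentile_cap(self, grid_factory):
        rng = np.random.default_rng(4)
        data = rng.uniform(5, 15, (20, 20))
        data[0, 0] = 500.0  # wild outlier in the left division
        chm = grid_factory(data, nodata=float("nan"))
        zones = {"west": box(0, 0, 100, 200), "east": box(100, 0, 200, 200)}
        out = apply_calibration(chm, _model(), zones)
        west = out.data[:, :10]
        cap = np.percentile(np.where(np.isnan(west), -np.inf, west), 100)  # realized max
        assert out.data[0, 0] < 500.0
        assert np.nanmax(out.data[:, 10:]) <= 15.0

    def test_monotone_within_division(self, grid_factory):
        rng = np.random.default_rng(9)
        data = rng.uniform(1, 30, (10, 10))
        chm = grid_factory(data, nodata=float("nan"))
        out = apply_calibration(chm, _model(slope=1.1, intercept=0.5), {"z": box(0, 0, 100, 100)})
        vals = out.data[~np.isnan(out.data)]
        raws = data[~np.isnan(out.data)]
        order = np.argsort(raws)
        assert (np.diff(vals[order]) >= -1e-12).all()


class TestHeightSummary:
    def test_constant_division(self, grid_factory):
        chm = grid_factory(np.full((10, 10), 7.0), nodata=float("nan"))
        rows = height_summary(chm, {"d": box(0, 0, 100, 100)})
        r = rows.iloc[0]
        assert (r["mean_m"], r["max_m"], r["mean_above_threshold_m"]) == (7.0, 7.0, 7.0)

    def test_mixed_heights_arithmetic(self, grid_factory):
        data = np.empty((10, 10))
        data[:5] = 3.0
        data[5:] = 9.0
        chm = grid_factory(data, nodata=float("nan"))
        r = height_summary(chm, {"d": box(0, 0, 100, 100)}).iloc[0]
        assert r["mean_m"] == pytest.approx(6.0)
        assert r["mean_above_threshold_m"] == pytest.approx(9.0)

    def test_mean_above_threshold_dominates_mean(self, grid_factory):
        rng = np.random.default_rng(13)
        for _ in range(10):
            data = rng.uniform(2.2, 20, (10, 10))
            chm = grid_factory(data, nodata=float("nan"))
            r = height_summary(chm, {"d": box(0, 0, 100, 100)}).iloc[0]
            if (data <= 5.0).any() and (data > 5.0).any():
                assert r["mean_above_threshold_m"] >= r["mean_m"]

    def test_empty_division_warns_and_blanks(self, grid_factory):
        chm = grid_factory(np.full((10, 10), np.nan), nodata=float("nan"))
        with pytest.warns(UserWarning):
            rows = height_summary(chm, {"d": box(0, 0, 100, 100)})
        assert np.isnan(rows.iloc[0]["mean_m"])


def test_full_bias_recovery_loop(default_scene):
    """Simulated canopy bias (slope 0.8) is recovered by the plot calibration."""
    from tofscape.classify import classify_tof
    from tofscape.compositing import composite_sar, greenest_composite
    from tofscape.synthetic import render_dsm, render_optical_series, render_sar_series, sample_gcps
    from tofscape.terrain import build_dtm, canopy_height

    params, truth = default_scene
    dsm, ref = render_dsm(truth, params)
    gcps, hold = sample_gcps(truth, 820, 40, seed=params.seed)
    dtm = build_dtm(gcps, hold, truth.terrain, radius=300.0).dtm
    mask = truth.tof_mask()
    chm = canopy_height(dsm, dtm, mask)
    ref_chm = canopy_height(ref, dtm, mask)
    model = fit_calibration(aggregate_plots(chm, ref_chm, mask))
    assert model.slope == pytest.approx(1 / 0.8, rel=0.08)
    assert model.mae_after <= 0.6
    assert model.mae_after <= model.mae_before
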