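"""End-to-end pipeline orchestration.

Runs simulate -> composite -> classify -> patches -> dtm -> chm ->
calibrate -> account -> accuracy in a fixed topological order, writes every
product to disk and records a manifest (parameters, output hashes,
versions) sufficient to reproduce any stage.  Deterministic stages are
bit-identical under a repeated run with the same config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .accounting import (
    division_summary,
    stratified_accuracy,
    stratified_sample_points,
    stratum_mapped_areas,
    validate_points,
)
from .calibration import apply_calibration, aggregate_plots, fit_calibration, height_summary
from .classify import ThresholdConfig, classify_tof
from .compositing import composite_sar, greenest_composite, DEFAULT_SCANLINE_THRESHOLD_DB
from .grid import RasterGrid
from .patches import label_patches, patch_table, size_class_summary
from .synthetic import (
    SceneParams,
    generate_landscape,
    render_dsm,
    render_optical_series,
    render_sar_series,
    sample_gcps,
)
from .terrain import build_dtm, canopy_height
from .vector import write_geojson

log = logging.getLogger("tofscape")

STAGES = (
    "simulate",
    "composite",
    "classify",
    "patches",
    "dtm",
    "chm",
    "calibrate",
    "account",
    "accuracy",
)


@dataclass
class RunConfig:
    """Everything one pipeline run needs, loadable from YAML."""

    out_dir: str = "tofscape_run"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    scene: SceneParams = field(default_factory=SceneParams)
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    scanline_threshold_db: float = DEFAULT_SCANLINE_THRESHOLD_DB
    idw_power: float = 2.0
    # local neighbourhood keeps the interpolated terrain from oversmoothing
    # at this GCP density; set None to weight every GCP (the tool convention)
    idw_radius: float | None = 300.0
    n_gcp: int = 820
    n_gcp_holdout: int = 40
    points_per_class: int = 60
    buffer_m: float = 10.0

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        # keep the fixed topological order regardless of input order
        self.stages = [s for s in STAGES if s in self.stages]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        scene = SceneParams(**{
            **doc.pop("scene", {}),
        })
        if "shape" in dataclasses.asdict(scene):
            scene.shape = tuple(scene.shape)
        scene.optical_dates = tuple(scene.optical_dates)
        scene.sar_dates = tuple(scene.sar_dates)
        scene.dsm_canopy_bias = tuple(scene.dsm_canopy_bias)
        scene.reference_bias = tuple(scene.reference_bias)
        thresholds = ThresholdConfig(**doc.pop("thresholds", {}))
        return cls(scene=scene, thresholds=thresholds, **doc)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(config: RunConfig) -> dict:
    """Execute the configured stages and return the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.scene.seed = config.seed
    outputs: dict[str, str] = {}
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stages": config.stages,
        "parameters": {
            "scene": dataclasses.asdict(config.scene),
            "thresholds": dataclasses.asdict(config.thresholds),
            "idw_power": config.idw_power,
            "idw_radius": config.idw_radius,
            "n_gcp": config.n_gcp,
            "n_gcp_holdout": config.n_gcp_holdout,
            "points_per_class": config.points_per_class,
            "buffer_m": config.buffer_m,
            "scanline_threshold_db": config.scanline_threshold_db,
        },
        "outputs": outputs,
    }

    def _emit(name: str, path: Path) -> None:
        outputs[name] = _sha256(path)

    state: dict = {}

    def _stage(name: str) -> bool:
        return name in config.stages

    try:
        # every later stage needs the truth; regenerate deterministically
        truth = generate_landscape(config.scene)
        state["truth"] = truth

        if _stage("simulate"):
            log.info("simulate: rendering scene inputs")
            truth.tree_mask.write(out / "truth_tree_mask.tif")
            truth.tree_height.write(out / "truth_tree_height.tif")
            truth.terrain.write(out / "truth_terrain.tif")
            write_geojson(
                out / "divisions.geojson",
                [({"division": k}, v) for k, v in truth.division_polygons.items()],
            )
            write_geojson(
                out / "forest_exclusion.geojson",
                [({"kind": "forest"}, g) for g in truth.forest_exclusion],
            )
            for name in ("truth_tree_mask", "truth_tree_height", "truth_terrain"):
                _emit(name, out / f"{name}.tif")
            _emit("divisions", out / "divisions.geojson")

        optical = render_optical_series(truth, config.scene)
        asc, desc = render_sar_series(truth, config.scene)
        dsm, reference = render_dsm(truth, config.scene)
        if _stage("simulate"):
            dsm.write(out / "dsm.tif")
            reference.write(out / "reference_surface.tif")
            _emit("dsm", out / "dsm.tif")
            _emit("reference_surface", out / "reference_surface.tif")

        if not any(_stage(s) for s in STAGES[1:]):
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            return manifest

        log.info("composite: greenest optical + linear-mean SAR")
        opt = greenest_composite(optical)
        sar = composite_sar(asc, desc, config.scanline_threshold_db)
        if _stage("composite"):
            opt.ndvi.write(out / "ndvi_composite.tif")
            sar.vh_db.write(out / "vh_mean_db.tif")
            sar.vv_db.write(out / "vv_mean_db.tif")
            sar.fill_flag.write(out / "scanline_fill_flag.tif")
            for name in ("ndvi_composite", "vh_mean_db", "vv_mean_db", "scanline_fill_flag"):
                _emit(name, out / f"{name}.tif")

        log.info("classify: threshold fusion + exclusion + sieve")
        tof = classify_tof(
            opt.ndvi, sar.vh_db, sar.vv_db, truth.forest_exclusion, config.thresholds
        )
        state["tof"] = tof
        if _stage("classify"):
            tof.write(out / "tof_mask.tif")
            _emit("tof_mask", out / "tof_mask.tif")

        if _stage("patches"):
            log.info("patches: connected-component size distribution")
            labels = label_patches(tof)
            table = patch_table(labels)
            summary = size_class_summary(table)
            labels.write(out / "patch_labels.tif")
            table.to_csv(out / "patch_table.csv", index=False)
            summary.to_csv(out / "patch_summary.csv", index=False)
            for name in ("patch_table", "patch_summary"):
                _emit(name, out / f"{name}.csv")

        gcps, holdout = sample_gcps(truth, config.n_gcp, config.n_gcp_holdout, config.seed)
        if _stage("dtm"):
            log.info("dtm: IDW interpolation from %d GCPs", len(gcps))
            dtm_result = build_dtm(
                gcps, holdout, truth.terrain, power=config.idw_power, radius=config.idw_radius
            )
            state["dtm"] = dtm_result.dtm
            gcps.to_csv(out / "gcps.csv")
            holdout.to_csv(out / "gcps_holdout.csv")
            dtm_result.dtm.write(out / "dtm.tif")
            dtm_result.to_json(out / "dtm_validation.json")
            _emit("dtm", out / "dtm.tif")
            _emit("dtm_validation", out / "dtm_validation.json")

        if _stage("chm"):
            dtm = state.get("dtm")
            if dtm is None:
                dtm_result = build_dtm(
                    gcps, holdout, truth.terrain, power=config.idw_power, radius=config.idw_radius
                )
                dtm = dtm_result.dtm
                state["dtm"] = dtm
            log.info("chm: DSM - DTM over the tree mask")
            chm = canopy_height(dsm, dtm, tof)
            state["chm"] = chm
            chm.write(out / "chm_raw.tif")
            _emit("chm_raw", out / "chm_raw.tif")

        if _stage("calibrate"):
            chm = state["chm"]
            log.info("calibrate: 1 ha plot aggregation + OLS correction")
            # the reference canopy surface is differenced against the same
            # terrain model so both sides of the regression are heights
            reference_chm = canopy_height(reference, state.get("dtm", truth.terrain), tof)
            plots = aggregate_plots(chm, reference_chm, tof)
            model = fit_calibration(plots)
            chm_cal = apply_calibration(chm, model, truth.division_polygons)
            state["chm_cal"] = chm_cal
            plots.to_csv(out / "plot_stats.csv", index=False)
            model.to_json(out / "calibration_model.json")
            chm_cal.write(out / "chm_calibrated.tif")
            heights = height_summary(chm_cal, truth.division_polygons)
            heights.to_csv(out / "height_summary.csv", index=False)
            for name in ("plot_stats", "height_summary"):
                _emit(name, out / f"{name}.csv")
            _emit("calibration_model", out / "calibration_model.json")
            _emit("chm_calibrated", out / "chm_calibrated.tif")

        if _stage("account"):
            log.info("account: per-division areas")
            summary = division_summary(tof, truth.division_polygons)
            summary.to_csv(out / "division_summary.csv", index=False)
            _emit("division_summary", out / "division_summary.csv")

        if _stage("accuracy"):
            log.info("accuracy: stratified validation sample")
            pts = stratified_sample_points(
                tof, truth.division_polygons, config.points_per_class, config.seed
            )
            truth_mask = truth.tof_mask()
            r, c = truth_mask.xy_to_rowcol(pts["x"].to_numpy(), pts["y"].to_numpy())
            pts["ref_label"] = truth_mask.data[r, c]
            counts, n_excl = validate_points(tof, pts, config.buffer_m)
            report = stratified_accuracy(
                counts,
                stratum_mapped_areas(tof, truth.division_polygons),
                n_points_excluded=n_excl,
            )
            report.to_json(out / "accuracy_report.json")
            _emit("accuracy_report", out / "accuracy_report.json")
    except Exception as exc:  # noqa: BLE001 - annotate and re-raise per contract
        manifest["failed"] = True
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
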