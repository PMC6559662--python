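"""End-to-end orchestration: scene -> index selection -> vine detection ->
segmentation/classification -> validation -> prescription.

Driven by a single YAML/dict configuration; every stage's artifact is
written to the output directory so stages can be re-consumed independently,
and a machine-readable run report records versions, seeds, parameters and
per-stage outcomes. The run needs no interactive input; on a stage failure
the partial outputs are kept and a ``FAILED`` marker names the stage.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import __version__, indices, prescription, raster_io, segmentation
from . import separability as sep
from . import synthetic, validation, vine
from .errors import ConfigurationError, PipelineError

log = logging.getLogger(__name__)

#: per-camera index used when selection mode is "fixed" (the separability
#: winners for each band set)
FIXED_INDEX = {"RGB": "ExGR", "RGNIR": "GNDVI"}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    return cfg


def _load_scene(cfg, outdir):
    if "synthetic" in cfg:
        spec = synthetic.SceneSpec(**(cfg["synthetic"] or {}))
        scene, labels = synthetic.generate_scene(spec)
        return scene, labels
    scene_cfg = cfg.get("scene")
    if not scene_cfg:
        raise ConfigurationError("config needs a 'scene' or 'synthetic' section")
    scene = raster_io.read_scene(scene_cfg["path"], scene_cfg.get("band_map"),
                                 scene_cfg.get("camera", "RGB"))
    labels = None
    if cfg.get("ground_truth"):
        labels = raster_io.read_labels(cfg["ground_truth"], scene)
    return scene, labels


def _select_index(cfg, scene, labels, outdir, report):
    mode = str(cfg.get("index", {}).get("mode", "fixed"))
    if mode.startswith("fixed:"):
        return mode.split(":", 1)[1], None
    if mode == "fixed":
        return FIXED_INDEX[scene.camera], None
    if mode != "auto":
        raise ConfigurationError(f"index mode must be fixed[:NAME] or auto, got {mode!r}")
    icfg = cfg.get("index", {})
    if icfg.get("samples"):
        samples = sep.read_sample_table(icfg["samples"], camera=scene.camera)
    elif labels is not None:
        samples = synthetic.sample_spectra(scene, labels,
                                           fraction=icfg.get("fraction", 0.25),
                                           seed=icfg.get("seed", cfg.get("seed", 0)))
    else:
        raise ConfigurationError("index mode 'auto' needs samples or ground truth")
    results, selected = sep.rank_indices(samples)
    table = sep.separability_report(results)
    table.to_csv(outdir / "separability.csv", index=False)
    report["separability"] = {
        "selected": selected,
        "top": table.to_dict(orient="records"),
    }
    return selected, results


def run_pipeline(config, outdir=None) -> dict:
    """Run every stage; returns (and writes) the run report."""
    cfg = load_config(config) if not isinstance(config, dict) else config
    outdir = Path(outdir or cfg.get("output_dir", "vineweed_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    report = {"version": __version__, "seed": cfg.get("seed", 0),
              "stages": {}, "config": _jsonable(cfg)}
    stage = "scene"
    t_all = time.perf_counter()
    try:
        t0 = time.perf_counter()
        scene, labels = _load_scene(cfg, outdir)
        report["stages"]["scene"] = {"shape": list(scene.shape),
                                     "camera": scene.camera,
                                     "pixel_size_m": scene.transform.pixel_size,
                                     "seconds": time.perf_counter() - t0}

        stage = "index_selection"
        t0 = time.perf_counter()
        index_name, _ = _select_index(cfg, scene, labels, outdir, report)
        index = indices.compute_index(scene, index_name)
        report["stages"]["index_selection"] = {"index": index_name,
                                               "seconds": time.perf_counter() - t0}

        stage = "vine_detection"
        t0 = time.perf_counter()
        vcfg = {**vine.DEFAULTS, **(cfg.get("vine") or {})}
        vcfg.pop("soil_quantile", None)
        vine_mask = vine.detect_vines(scene, **vcfg)
        report["stages"]["vine_detection"] = {
            "vine_pixels": int(vine_mask.mask.sum()),
            "seconds": time.perf_counter() - t0}

        stage = "classification"
        t0 = time.perf_counter()
        params = segmentation.SegmentationParams(**(cfg.get("segmentation") or {}))
        domain = ~vine_mask.mask & ~scene.nodata_mask
        segments = segmentation.multiresolution_segment(scene, domain, params)
        classified = segmentation.classify_objects(
            segments, index, vine_mask, transform=scene.transform, crs=scene.crs,
            nodata_mask=scene.nodata_mask)
        raster_io.write_classified(classified, outdir / "classified.tif")
        with open(outdir / "area_summary.json", "w") as fh:
            json.dump(classified.area_summary, fh, indent=2)
        report["stages"]["classification"] = {
            "n_objects": segments.n_objects,
            "threshold": classified.threshold_used,
            "area_summary": classified.area_summary,
            "seconds": time.perf_counter() - t0}

        stage = "validation"
        t0 = time.perf_counter()
        if labels is not None:
            cm = validation.confusion_matrix(classified, labels)
            with open(outdir / "confusion.json", "w") as fh:
                json.dump(cm.report(), fh, indent=2)
            report["stages"]["validation"] = {**cm.report(),
                                              "seconds": time.perf_counter() - t0}
        else:
            log.info("no ground truth configured; validation stage skipped")
            report["stages"]["validation"] = {"skipped": True}

        stage = "prescription"
        t0 = time.perf_counter()
        pcfg = prescription.PrescriptionConfig(**(cfg.get("prescription") or {}))
        grid = prescription.build_grid(classified, pcfg)
        grid = prescription.compute_coverage(grid, classified)
        grid = prescription.apply_thresholds(grid)
        raster_io.write_grid_geojson(grid, outdir / "treatment_grid.geojson")
        savings = prescription.savings_report(grid)
        with open(outdir / "savings.json", "w") as fh:
            json.dump(savings, fh, indent=2)
        report["stages"]["prescription"] = {**savings,
                                            "seconds": time.perf_counter() - t0}
    except Exception as exc:
        (outdir / "FAILED").write_text(f"{stage}: {exc}\n")
        report["failed_stage"] = stage
        with open(outdir / "report.json", "w") as fh:
            json.dump(_jsonable(report), fh, indent=2)
        raise PipelineError(stage, str(exc)) from exc

    report["seconds_total"] = time.perf_counter() - t_all
    with open(outdir / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2)
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    return obj
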