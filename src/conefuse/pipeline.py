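"""Configuration schema and the end-to-end fusion pipeline.

Stages: detect → calibrate → locate-markers → extract-plane → register →
score.  Every intermediate artifact is written in a plain format
(TIFF/CSV/JSON/PNG) and the run is deterministic given the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields
from contextlib import contextmanager
from pathlib import Path

import numpy as np
import yaml
from skimage import transform as sktransform

from . import io as cio
from .calibrate import ConeTrack, TaperModel, cluster_detections, filter_outliers, fit_taper
from .detect import DetectionParams, detect_ellipses_slice, sample_slice_indices
from .histology import HistologyPreprocess, detect_section_ellipses, match_to_cones
from .matching import match_positions
from .metrics import (RegistrationParams, RigidTransform2D, apply_rigid, lncc,
                      lncc_layer_sweep, overlay_checkerboard, rigid_register)
from .plane import embedding_from_markers, extract_oblique_slice

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and a remediation hint."""

    def __init__(self, stage: str, message: str, hint: str = ""):
        self.stage = stage
        super().__init__(f"[{stage}] {message}" + (f" (hint: {hint})" if hint else ""))


def _from_mapping(cls, data: dict, where: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown keys {sorted(unknown)} in config section {where!r}; "
                         f"allowed: {sorted(allowed)}")
    return cls(**data)


@dataclass(frozen=True)
class InputConfig:
    path: str
    voxel_size: float | None = None
    pixel_size: float | None = None


@dataclass(frozen=True)
class DetectConfig:
    n_sample: int = 100
    block_size: int = 51
    adaptive_offset: float = 0.02
    canny_low: float = 0.1
    canny_high: float = 0.3
    morph_radius: int = 2
    min_area_px2: float = 30.0
    max_area_px2: float | None = None
    max_eccentricity: float = 0.9

    def detection_params(self) -> DetectionParams:
        return DetectionParams(
            block_size=self.block_size, adaptive_offset=self.adaptive_offset,
            canny_low=self.canny_low, canny_high=self.canny_high,
            morph_radius=self.morph_radius, min_area_px2=self.min_area_px2,
            max_area_px2=self.max_area_px2, max_eccentricity=self.max_eccentricity)


@dataclass(frozen=True)
class CalibrateConfig:
    distance_threshold_px: float | None = None   # None → 3 x median major axis
    width_bounds_mm: tuple[float, float] | None = None
    residual_threshold_mm: float | None = None   # None → 3 x scaled MAD


@dataclass(frozen=True)
class HistologyConfig:
    saturation_threshold: float = 0.75
    channel: str = "auto"
    invert: bool = False
    min_area_px2: float = 30.0
    max_eccentricity: float = 0.9


@dataclass(frozen=True)
class MetricConfig:
    window: int = 45
    layer_sweep: bool = False
    checkerboard_tile: int = 32


@dataclass(frozen=True)
class RegisterConfig:
    rotation_range: float = 6.0
    rotation_step: float = 1.0
    translation_range: float = 12.0
    levels: int = 3

    def registration_params(self) -> RegistrationParams:
        return RegistrationParams(rotation_range=self.rotation_range,
                                  rotation_step=self.rotation_step,
                                  translation_range=self.translation_range,
                                  levels=self.levels)


@dataclass(frozen=True)
class PipelineConfig:
    volume: InputConfig
    section: InputConfig
    layout: dict
    out_dir: str
    seed: int = 0
    detect: DetectConfig = field(default_factory=DetectConfig)
    calibrate: CalibrateConfig = field(default_factory=CalibrateConfig)
    histology: HistologyConfig = field(default_factory=HistologyConfig)
    metric: MetricConfig = field(default_factory=MetricConfig)
    register: RegisterConfig = field(default_factory=RegisterConfig)

    @classmethod
    def from_mapping(cls, data: dict) -> "PipelineConfig":
        allowed = {f.name for f in fields(cls)}
        unknown = set(data) - allowed
        if unknown:
            raise ValueError(f"unknown top-level config keys {sorted(unknown)}; "
                             f"allowed: {sorted(allowed)}")
        for key in ("volume", "section", "layout", "out_dir"):
            if key not in data:
                raise ValueError(f"config is missing required key {key!r}")
        kw = dict(data)
        kw["volume"] = _from_mapping(InputConfig, dict(data["volume"]), "volume")
        kw["section"] = _from_mapping(InputConfig, dict(data["section"]), "section")
        for name, sub in (("detect", DetectConfig), ("calibrate", CalibrateConfig),
                          ("histology", HistologyConfig), ("metric", MetricConfig),
                          ("register", RegisterConfig)):
            if name in kw:
                d = dict(kw[name])
                if name == "calibrate" and d.get("width_bounds_mm") is not None:
                    d["width_bounds_mm"] = tuple(d["width_bounds_mm"])
                kw[name] = _from_mapping(sub, d, name)
        kw["layout"] = {str(k): (float(v[0]), float(v[1])) for k, v in data["layout"].items()}
        return cls(**kw)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return PipelineConfig.from_mapping(data)


@contextmanager
def _stage(name: str, hint: str = ""):
    logger.info("stage %s: start", name)
    try:
        yield
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(name, str(exc), hint) from exc
    logger.info("stage %s: done", name)


def calibrate_tracks(
    detections,
    layout: dict,
    pixel_size: float,
    cfg: CalibrateConfig = CalibrateConfig(),
) -> dict[str, TaperModel]:
    """Cluster detections, name tracks after the layout, filter, fit tapers."""
    tracks = cluster_detections(detections, n_cones=len(layout))
    means = np.array([t.mean_center for t in tracks])
    ids = match_positions(means, layout)
    tapers: dict[str, TaperModel] = {}
    for cone_id, ti in ids.items():
        track = ConeTrack(cone_id=cone_id, detections=tracks[ti].detections)
        thr = cfg.distance_threshold_px
        if thr is None:
            thr = 3.0 * float(np.median([d.major_axis for d in track.detections]))
        track = filter_outliers(track, thr, cfg.width_bounds_mm, pixel_size)
        tapers[cone_id] = fit_taper(track, pixel_size, cfg.residual_threshold_mm)
    return tapers


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full fusion pipeline; returns (and writes) the summary report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with _stage("read-inputs", "check paths and voxel/pixel sizes in the config"):
        volume = cio.read_volume(config.volume.path, config.volume.voxel_size)
        section, pixel_size = cio.read_section_image(
            config.section.path, config.section.pixel_size)

    with _stage("detect", "lower min_area_px2 or the adaptive offset if markers are missed"):
        params = config.detect.detection_params()
        idx = sample_slice_indices(volume.n_slices, config.detect.n_sample, config.seed)
        detections = []
        for k in idx:
            detections.extend(detect_ellipses_slice(volume.slice(int(k)), params,
                                                    slice_index=int(k)))
        cio.write_detections_csv(out / "detections.csv", detections)
        logger.info("detect: %d detections on %d slices", len(detections), len(idx))

    with _stage("calibrate", "check the layout positions and clustering thresholds"):
        tapers = calibrate_tracks(detections, config.layout, volume.voxel_size,
                                  config.calibrate)
        cio.write_calibration(out / "calibration.json", tapers)

    with _stage("locate-markers", "tune histology saturation_threshold / filters"):
        prep = HistologyPreprocess(channel=config.histology.channel,
                                   saturation_threshold=config.histology.saturation_threshold,
                                   invert=config.histology.invert)
        hist_params = DetectionParams(min_area_px2=config.histology.min_area_px2,
                                      max_eccentricity=config.histology.max_eccentricity)
        ellipses = detect_section_ellipses(section, hist_params, prep,
                                           n_expected=len(config.layout))
        markers = match_to_cones(ellipses, config.layout, pixel_size)
        (out / "markers.json").write_text(json.dumps({
            cid: {"center_px": list(e.center), "major_px": e.major_axis,
                  "minor_px": e.minor_axis, "angle_deg": e.angle}
            for cid, e in markers.assignment.items()}, indent=2, sort_keys=True))

    with _stage("extract-plane", "verify the calibration covers the measured widths"):
        embedding = embedding_from_markers(markers, tapers, volume.voxel_size)
        scale = pixel_size / volume.voxel_size
        out_shape = (max(int(round(section.shape[0] * scale)), 8),
                     max(int(round(section.shape[1] * scale)), 8))
        plane_img = extract_oblique_slice(volume, embedding, out_shape)
        cio.write_section_image(out / "plane.tif", plane_img, volume.voxel_size)
        (out / "plane.json").write_text(json.dumps(embedding.to_dict(), indent=2,
                                                   sort_keys=True))

    with _stage("register", "increase the search ranges if the initial guess is far off"):
        moving = sktransform.resize(np.asarray(section, dtype=np.float64), out_shape,
                                    anti_aliasing=True)
        transform = rigid_register(moving, plane_img,
                                   params=config.register.registration_params())
        (out / "transform.json").write_text(json.dumps({
            "rotation_deg": transform.rotation,
            "translation_px": list(transform.translation),
            "scale": transform.scale}, indent=2, sort_keys=True))

    with _stage("score", "ensure the section overlaps the extracted plane"):
        warped = apply_rigid(moving, transform, output_shape=plane_img.shape, cval=np.nan)
        fixed = np.asarray(plane_img, dtype=np.float64)
        filled = np.where(np.isfinite(warped), warped, fixed.mean())
        result = lncc(fixed, filled, config.metric.window)
        cio.write_section_image(out / "lncc_heatmap.tif", result.heatmap,
                                volume.voxel_size)
        lo, hi = filled.min(), filled.max()
        board = overlay_checkerboard(
            (fixed - fixed.min()) / max(fixed.max() - fixed.min(), 1e-30),
            (filled - lo) / max(hi - lo, 1e-30), config.metric.checkerboard_tile)
        cio.write_section_image(out / "checkerboard.png", board, volume.voxel_size)
        sweep = None
        if config.metric.layer_sweep:
            scores, best = lncc_layer_sweep(volume, filled, config.metric.window)
            sweep = {"best_layer": best, "scores": [float(s) for s in scores]}
            with open(out / "layer_sweep.csv", "w") as fh:
                fh.write("layer,lncc_mean\n")
                fh.writelines(f"{k},{s:.8f}\n" for k, s in enumerate(scores))

    summary = {
        "seed": config.seed,
        "n_detections": len(detections),
        "tapers": {cid: m.to_dict() for cid, m in sorted(tapers.items())},
        "plane": embedding.to_dict(),
        "transform": {"rotation_deg": transform.rotation,
                      "translation_px": list(transform.translation),
                      "scale": transform.scale},
        "lncc": {"window": config.metric.window, "mean": result.mean_lncc,
                 "max": result.max_lncc},
    }
    if sweep is not None:
        summary["layer_sweep"] = sweep
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
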