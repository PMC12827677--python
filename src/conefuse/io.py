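"""Plain-format readers and writers: multi-page TIFF volumes with JSON
sidecars, section images, detection CSVs, calibration JSON.

All intermediates are readable without this package (TIFF/CSV/JSON/PNG).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .calibrate import TaperModel
from .detect import EllipseDetection
from .volume import VoxelVolume

__all__ = ["read_volume", "write_volume", "read_section_image", "write_section_image",
           "write_detections_csv", "read_detections_csv", "write_calibration",
           "read_calibration"]

_DETECTION_COLUMNS = ["slice_index", "cx", "cy", "major", "minor", "angle", "source"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def read_volume(path: str | Path, voxel_size: float | None = None) -> VoxelVolume:
    """Read a multi-page TIFF (or a directory of numbered single-page TIFFs).

    Voxel size comes from the ``<file>.json`` sidecar unless given
    explicitly.  Slices in a directory are stacked in sorted filename
    order; inconsistent slice shapes raise, naming the offending file.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in {".tif", ".tiff"})
        if not files:
            raise FileNotFoundError(f"no TIFF slices in {path}")
        slices = []
        shape0 = None
        for f in files:
            sl = tifffile.imread(f)
            if shape0 is None:
                shape0 = sl.shape
            elif sl.shape != shape0:
                raise ValueError(
                    f"slice {f.name} has shape {sl.shape}, expected {shape0}")
            slices.append(sl)
        data = np.stack(slices)
        sidecar = path / "volume.json"
    else:
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        sidecar = _sidecar(path)
    if voxel_size is None:
        if not sidecar.exists():
            raise ValueError(
                f"voxel size not given and sidecar {sidecar} not found")
        voxel_size = json.loads(sidecar.read_text())["voxel_size_mm"]
    return VoxelVolume(data, float(voxel_size))


def write_volume(path: str | Path, volume: VoxelVolume,
                 extra_meta: Mapping | None = None) -> None:
    """Write a float32 multi-page TIFF plus a JSON sidecar with the voxel size."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, volume.data.astype(np.float32), photometric="minisblack")
    meta = {"voxel_size_mm": volume.voxel_size, "shape_zyx": list(volume.shape)}
    if extra_meta:
        meta.update(extra_meta)
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_section_image(path: str | Path, pixel_size: float | None = None
                       ) -> tuple[np.ndarray, float]:
    """Read a 2D section image (PNG/TIFF); pixel size from sidecar or flag."""
    path = Path(path)
    img = iio.imread(path)
    if pixel_size is None:
        sidecar = _sidecar(path)
        if not sidecar.exists():
            raise ValueError(f"pixel size not given and sidecar {sidecar} not found")
        pixel_size = json.loads(sidecar.read_text())["pixel_size_mm"]
    return np.asarray(img), float(pixel_size)


def write_section_image(path: str | Path, image: np.ndarray, pixel_size: float) -> None:
    """Write a section image (16-bit for PNG, float32 for TIFF) with a pixel-size sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = np.asarray(image)
    if path.suffix.lower() == ".png":
        lo, hi = float(img.min()), float(img.max())
        scaled = np.zeros_like(img, dtype=np.uint16) if hi == lo else (
            np.round((img - lo) / (hi - lo) * 65535).astype(np.uint16))
        iio.imwrite(path, scaled)
    else:
        tifffile.imwrite(path, img.astype(np.float32))
    _sidecar(path).write_text(json.dumps({"pixel_size_mm": pixel_size}, indent=2))


def write_detections_csv(path: str | Path, detections: list[EllipseDetection]) -> None:
    rows = [{"slice_index": d.slice_index, "cx": d.center[0], "cy": d.center[1],
             "major": d.major_axis, "minor": d.minor_axis, "angle": d.angle,
             "source": d.source} for d in detections]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=_DETECTION_COLUMNS).to_csv(path, index=False)


def read_detections_csv(path: str | Path) -> list[EllipseDetection]:
    df = pd.read_csv(path)
    missing = set(_DETECTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"detections CSV {path} missing columns {sorted(missing)}")
    return [EllipseDetection(slice_index=int(r.slice_index), center=(r.cx, r.cy),
                             major_axis=r.major, minor_axis=r.minor, angle=r.angle,
                             source=r.source)
            for r in df.itertuples()]


def write_calibration(path: str | Path, tapers: Mapping[str, TaperModel]) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(
        {cid: m.to_dict() for cid, m in tapers.items()}, indent=2, sort_keys=True))


def read_calibration(path: str | Path) -> dict[str, TaperModel]:
    raw = json.loads(Path(path).read_text())
    return {cid: TaperModel.from_dict(d) for cid, d in raw.items()}
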