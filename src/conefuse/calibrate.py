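"""Per-cone taper calibration from slice-wise ellipse detections.

Detections from the sampled slices are clustered by center position into
one track per cone (upright markers keep a near-constant center through
the stack), spatial and width outliers are removed, and each track's
width-vs-slice-index relation is fitted with a two-pass linear regression:
an ordinary least-squares fit, rejection of points whose residual exceeds
a robust threshold, and a refit on the survivors.  The fitted line is the
calibration that maps a measured section width back to a continuous
z-position, interpolating across the slices that were never sampled; a
per-axis linear center-drift fit does the same for the axis position
(absorbing small marker tilt).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

from .detect import EllipseDetection

__all__ = ["ConeTrack", "TaperModel", "cluster_detections", "filter_outliers",
           "fit_taper", "width_to_height"]


class ClusteringError(ValueError):
    pass


@dataclass
class ConeTrack:
    """Detections attributed to one cone, with inlier bookkeeping."""

    cone_id: str
    detections: list[EllipseDetection]
    inlier: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.inlier is None:
            self.inlier = np.ones(len(self.detections), dtype=bool)
        self.inlier = np.asarray(self.inlier, dtype=bool)
        if self.inlier.shape != (len(self.detections),):
            raise ValueError("inlier flags must match detections")

    @property
    def inliers(self) -> list[EllipseDetection]:
        return [d for d, ok in zip(self.detections, self.inlier) if ok]

    @property
    def mean_center(self) -> tuple[float, float]:
        pts = np.array([d.center for d in self.inliers])
        if pts.size == 0:
            raise ValueError(f"track {self.cone_id!r} has no inliers")
        return (float(pts[:, 0].mean()), float(pts[:, 1].mean()))


def _centers(detections: Sequence[EllipseDetection]) -> np.ndarray:
    return np.array([d.center for d in detections], dtype=float)


def cluster_detections(
    detections: Sequence[EllipseDetection],
    n_cones: int = 3,
    distance_threshold: float | None = None,
    min_neighbors: int = 2,
) -> list[ConeTrack]:
    """Partition detections into ``n_cones`` spatial tracks by center proximity.

    A density filter (points with fewer than ``min_neighbors`` neighbours
    within an adaptive radius are excluded from centroid fitting) keeps
    isolated false positives from seeding clusters; k-means with
    farthest-point initialization then fits the centroids, every detection
    is assigned to its nearest centroid, and detections farther than
    ``distance_threshold`` from all centroids are left unassigned (dropped
    from the returned tracks).
    """
    detections = list(detections)
    if len({d.slice_index for d in detections}) < 2:
        raise ClusteringError("detections from at least 2 distinct slices required")
    pts = _centers(detections)
    n = len(pts)
    if n < n_cones:
        raise ClusteringError(f"only {n} detections; cannot form {n_cones} clusters")

    # density filter: adaptive neighbour radius from nearest-neighbour scale
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    nn = np.sqrt(d2.min(axis=1))
    r_density = 5.0 * np.median(nn) + 1e-9
    n_neighbors = (d2 <= r_density**2).sum(axis=1)
    dense = n_neighbors >= min_neighbors if n > n_cones else np.ones(n, bool)
    if dense.sum() < n_cones:
        dense = np.ones(n, bool)
    dpts = pts[dense]

    # farthest-point initialization on the dense subset
    init_idx = [int(np.argmax(np.linalg.norm(dpts - dpts.mean(axis=0), axis=1)))]
    while len(init_idx) < n_cones:
        dist_to_chosen = np.min(
            [np.linalg.norm(dpts - dpts[i], axis=1) for i in init_idx], axis=0)
        init_idx.append(int(np.argmax(dist_to_chosen)))
    km = KMeans(n_clusters=n_cones, init=dpts[init_idx], n_init=1, random_state=0)
    labels_dense = km.fit_predict(dpts)
    centroids = km.cluster_centers_
    achieved = len(np.unique(labels_dense))
    if achieved < n_cones:
        raise ClusteringError(
            f"found only {achieved} distinct clusters, {n_cones} requested")

    dist_all = np.linalg.norm(pts[:, None, :] - centroids[None, :, :], axis=-1)
    nearest = dist_all.argmin(axis=1)
    nearest_dist = dist_all.min(axis=1)
    if distance_threshold is None:
        within = np.linalg.norm(dpts - centroids[labels_dense], axis=1)
        distance_threshold = max(5.0 * float(np.median(within)),
                                 float(np.quantile(within, 0.95))) + 1e-9
    assigned = nearest_dist <= distance_threshold

    # order cone ids reproducibly by centroid position (x, then y)
    order = np.lexsort((centroids[:, 1], centroids[:, 0]))
    tracks = []
    for rank, ci in enumerate(order):
        members = [d for d, lab, ok in zip(detections, nearest, assigned) if ok and lab == ci]
        tracks.append(ConeTrack(cone_id=f"cone_{rank}", detections=members))
    if any(len(t.detections) == 0 for t in tracks):
        bad = sum(len(t.detections) > 0 for t in tracks)
        raise ClusteringError(f"found only {bad} non-empty clusters, {n_cones} requested")
    return tracks


def filter_outliers(
    track: ConeTrack,
    distance_threshold: float,
    width_bounds: tuple[float, float] | None = None,
    pixel_size: float = 1.0,
) -> ConeTrack:
    """Flag detections far from the track's mean center or outside width bounds.

    ``width_bounds`` are in mm (converted through ``pixel_size``); ``None``
    disables the width criterion.  The mean center is recomputed on the
    surviving inliers.  Raises if nothing survives.
    """
    if not track.detections:
        raise ValueError(f"track {track.cone_id!r} is empty")
    pts = _centers(track.detections)
    mean = pts[track.inlier].mean(axis=0)
    keep = np.linalg.norm(pts - mean, axis=1) <= distance_threshold
    if width_bounds is not None:
        w_mm = np.array([d.major_axis for d in track.detections]) * pixel_size
        keep &= (w_mm >= width_bounds[0]) & (w_mm <= width_bounds[1])
    if not keep.any():
        raise ValueError(
            f"all {len(track.detections)} detections of track {track.cone_id!r} "
            "flagged as outliers; check thresholds")
    return ConeTrack(cone_id=track.cone_id, detections=track.detections, inlier=keep)


@dataclass
class TaperModel:
    """Linear width↔height calibration of one cone.

    ``width_at(z) = slope * z + intercept`` with z a (continuous) slice
    index and width in mm; ``center_at(z)`` evaluates the per-axis linear
    center-drift fit (pixels).
    """

    cone_id: str
    slope: float                    # mm width per slice index (negative: tapers upward)
    intercept: float                # mm at slice index 0
    residual_threshold: float       # mm, pass-1 rejection level
    inlier_count: int
    pixel_size: float               # mm per pixel of the detection images
    center_drift: np.ndarray        # (2, 2): rows (slope, intercept) for cx, cy in px
    width_range_mm: tuple[float, float]  # calibrated width span (min, max)

    def width_at(self, z: float | np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(z, dtype=float) + self.intercept

    def z_at(self, width_mm: float, warn_extrapolation: bool = False) -> float:
        if self.slope == 0:
            raise ZeroDivisionError(f"taper model {self.cone_id!r} has zero slope")
        if warn_extrapolation and not (
                self.width_range_mm[0] - 1e-12 <= width_mm <= self.width_range_mm[1] + 1e-12):
            warnings.warn(
                f"width {width_mm:.4g} mm outside calibrated range "
                f"{self.width_range_mm} for {self.cone_id!r}; extrapolating",
                UserWarning, stacklevel=2)
        return (width_mm - self.intercept) / self.slope

    def center_at(self, z: float) -> tuple[float, float]:
        cx = self.center_drift[0, 0] * z + self.center_drift[0, 1]
        cy = self.center_drift[1, 0] * z + self.center_drift[1, 1]
        return (float(cx), float(cy))

    def to_dict(self) -> dict:
        return {
            "cone_id": self.cone_id, "slope_mm_per_slice": self.slope,
            "intercept_mm": self.intercept, "residual_threshold_mm": self.residual_threshold,
            "inlier_count": self.inlier_count, "pixel_size_mm": self.pixel_size,
            "center_drift_px": np.asarray(self.center_drift).tolist(),
            "width_range_mm": list(self.width_range_mm),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TaperModel":
        return cls(cone_id=d["cone_id"], slope=d["slope_mm_per_slice"],
                   intercept=d["intercept_mm"], residual_threshold=d["residual_threshold_mm"],
                   inlier_count=d["inlier_count"], pixel_size=d["pixel_size_mm"],
                   center_drift=np.array(d["center_drift_px"]),
                   width_range_mm=tuple(d["width_range_mm"]))


def fit_taper(
    track: ConeTrack,
    pixel_size: float,
    residual_threshold_mm: float | None = None,
) -> TaperModel:
    """Two-pass robust linear fit of width (mm) against slice index.

    Pass 1 fits ordinary least squares on the track's inliers; points with
    absolute residual above the threshold (default 3 x 1.4826 x MAD of the
    pass-1 residuals) are rejected; pass 2 refits on the survivors.  The
    per-axis center drift is fitted on the same surviving points, so axis
    position is interpolated across unsampled slices alongside the width.
    """
    dets = track.inliers
    z = np.array([d.slice_index for d in dets], dtype=float)
    if len(dets) < 2 or len(np.unique(z)) < 2:
        raise ValueError(
            f"track {track.cone_id!r}: need >= 2 inliers on >= 2 distinct slices")
    w = np.array([d.major_axis for d in dets]) * pixel_size

    slope1, inter1 = np.polyfit(z, w, 1)
    resid = w - (slope1 * z + inter1)
    # center on the median: gross outliers bias the pass-1 intercept, which
    # would otherwise offset every genuine point's residual
    centered = resid - np.median(resid)
    if residual_threshold_mm is None:
        mad = np.median(np.abs(centered))
        residual_threshold_mm = max(3.0 * 1.4826 * float(mad), 1e-9)
    keep = np.abs(centered) <= residual_threshold_mm
    if keep.sum() < 2 or len(np.unique(z[keep])) < 2:
        raise ValueError(
            f"track {track.cone_id!r}: fewer than 2 points survive the pass-1 "
            f"residual filter ({residual_threshold_mm:.4g} mm)")
    slope2, inter2 = np.polyfit(z[keep], w[keep], 1)
    if abs(slope2) < 1e-15:
        raise ValueError(f"track {track.cone_id!r}: fitted taper slope is zero")

    cx = np.array([d.center[0] for d in dets])
    cy = np.array([d.center[1] for d in dets])
    drift = np.array([np.polyfit(z[keep], cx[keep], 1), np.polyfit(z[keep], cy[keep], 1)])

    return TaperModel(
        cone_id=track.cone_id, slope=float(slope2), intercept=float(inter2),
        residual_threshold=float(residual_threshold_mm), inlier_count=int(keep.sum()),
        pixel_size=pixel_size, center_drift=drift,
        width_range_mm=(float(w[keep].min()), float(w[keep].max())),
    )


def width_to_height(model: TaperModel, width_mm: float) -> float:
    """Invert the calibration: measured width (mm) → continuous slice index.

    Warns when the width lies outside the calibrated range (extrapolation).
    """
    return model.z_at(width_mm, warn_extrapolation=True)
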