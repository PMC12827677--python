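"""Slice-wise detection of conic cross-sections.

The rule-based chain mirrors classical marker segmentation: adaptive
thresholding, Canny edge support, morphological opening and closing,
contour extraction and least-squares ellipse fitting, followed by size and
eccentricity filters.  A pluggable promptable-mask backend (point prompt →
binary mask) is also provided; the built-in backend is a seeded
threshold/flood segmenter, and any neural promptable segmenter can be
plugged in behind the same contract.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from skimage import feature, measure, morphology
from skimage.filters import threshold_local, threshold_otsu

logger = logging.getLogger(__name__)

__all__ = [
    "EllipseDetection",
    "DetectionParams",
    "sample_slice_indices",
    "detect_ellipses_slice",
    "segment_with_backend",
    "mask_to_ellipse",
    "ThresholdFloodBackend",
    "MaskBackend",
]


@dataclass(frozen=True)
class EllipseDetection:
    """One fitted conic cross-section.

    ``center`` is (x, y) in pixels; ``angle`` is the major-axis direction
    in degrees CCW from +x, in [0, 180); ``source`` is one of
    ``{"rule", "backend", "histology", "truth"}``.
    """

    slice_index: int
    center: tuple[float, float]
    major_axis: float
    minor_axis: float
    angle: float
    source: str = "rule"

    def __post_init__(self) -> None:
        if not self.major_axis >= self.minor_axis > 0:
            raise ValueError(
                f"need major_axis >= minor_axis > 0, got ({self.major_axis}, {self.minor_axis})")

    @property
    def eccentricity(self) -> float:
        return float(np.sqrt(1.0 - (self.minor_axis / self.major_axis) ** 2))

    @property
    def area(self) -> float:
        return float(np.pi * self.major_axis * self.minor_axis / 4.0)


@dataclass(frozen=True)
class DetectionParams:
    """Tunable parameters of the rule-based chain.

    Intensity-like values (``adaptive_offset``, Canny thresholds) are
    fractions of the image dynamic range, which makes detection invariant
    to global affine intensity rescaling.
    """

    block_size: int = 51               # adaptive-threshold neighbourhood, odd px
    adaptive_offset: float = 0.02      # threshold above local mean, fraction of range
    canny_sigma: float = 1.5
    canny_low: float = 0.1             # fraction of range
    canny_high: float = 0.3
    morph_radius: int = 2              # opening/closing structuring-disk radius, px
    min_area_px2: float = 30.0         # ellipse area bounds (pi * a * b / 4)
    max_area_px2: float | None = None  # None → a quarter of the image area
    max_eccentricity: float = 0.9
    min_contour_points: int = 15
    edge_support_fraction: float = 0.2  # boundary fraction that must lie on Canny edges

    def __post_init__(self) -> None:
        if self.block_size < 3 or self.block_size % 2 == 0:
            raise ValueError("block_size must be odd and >= 3")
        if not self.canny_low < self.canny_high:
            raise ValueError("canny_low must be < canny_high")
        if self.min_area_px2 <= 0 or (self.max_area_px2 is not None and self.max_area_px2 <= 0):
            raise ValueError("area bounds must be positive")


def params_for_cone_geometry(
    base_diameter_mm: float, apex_diameter_mm: float, pixel_size_mm: float, **overrides
) -> DetectionParams:
    """Detection parameters with area bounds derived from the marker design."""
    r_apex = apex_diameter_mm / (2 * pixel_size_mm)
    r_base = base_diameter_mm / (2 * pixel_size_mm)
    return DetectionParams(
        min_area_px2=0.25 * np.pi * r_apex**2,
        max_area_px2=4.0 * np.pi * r_base**2,
        **overrides,
    )


def sample_slice_indices(n_total: int, n_sample: int, seed: int) -> np.ndarray:
    """Draw ``n_sample`` unique, sorted slice indices out of ``n_total``.

    Deterministic per seed; sampling without replacement.
    """
    if not 0 < n_sample <= n_total:
        raise ValueError(f"need 0 < n_sample <= n_total, got {n_sample} of {n_total}")
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(n_total, size=n_sample, replace=False))


def _fit_ellipse_lsq(points_xy: np.ndarray) -> tuple[tuple[float, float], float, float, float] | None:
    """Algebraic least-squares ellipse fit; returns (center, major, minor, angle_deg)."""
    model = measure.EllipseModel.from_estimate(points_xy)
    if not model:
        return None
    (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    if not (np.isfinite([xc, yc, a, b, theta]).all() and a > 0 and b > 0):
        return None
    major, minor = 2 * max(a, b), 2 * min(a, b)
    ang = theta if a >= b else theta + np.pi / 2
    return (float(xc), float(yc)), float(major), float(minor), float(np.degrees(ang) % 180.0)


def detect_ellipses_slice(
    image: np.ndarray,
    params: DetectionParams = DetectionParams(),
    slice_index: int = 0,
    source: str = "rule",
) -> list[EllipseDetection]:
    """Run the rule-based chain on one 2D slice.

    Order of operations: adaptive threshold → Canny edge map (used as edge
    support: a candidate region is kept only if enough of its boundary lies
    on edges) → morphological opening, closing → per-region subpixel contour
    → least-squares ellipse fit → area / eccentricity / bounds filters.
    May still return false positives; cluster filtering removes them
    downstream.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("detect_ellipses_slice expects a 2D image")
    if min(img.shape) < params.block_size:
        raise ValueError(
            f"image shape {img.shape} smaller than adaptive block size {params.block_size}")
    rng_span = img.max() - img.min()
    if rng_span == 0:
        return []
    norm = (img - img.min()) / rng_span

    # adaptive threshold: foreground = locally bright by at least the offset
    local = threshold_local(norm, block_size=params.block_size, method="gaussian",
                            offset=-params.adaptive_offset)
    fg = norm > local

    edges = feature.canny(norm, sigma=params.canny_sigma,
                          low_threshold=params.canny_low, high_threshold=params.canny_high)
    edge_support = morphology.dilation(edges, morphology.disk(1))

    disk = morphology.disk(params.morph_radius)
    fg = morphology.opening(fg, disk)
    fg = morphology.closing(fg, disk)
    fg = morphology.remove_small_holes(fg, max_size=64)

    labels = measure.label(fg)
    max_area = params.max_area_px2 if params.max_area_px2 is not None else img.size / 4.0
    h, w = img.shape
    detections: list[EllipseDetection] = []
    for region in measure.regionprops(labels):
        if region.area < params.min_area_px2 / 2 or region.area > 2 * max_area:
            continue
        boundary = region.image ^ morphology.erosion(region.image)
        r0, c0, _, _ = region.bbox
        br, bc = np.nonzero(boundary)
        support = edge_support[br + r0, bc + c0].mean() if br.size else 0.0
        if support < params.edge_support_fraction:
            continue
        mask = np.pad(region.image, 1)
        contours = measure.find_contours(mask.astype(float), 0.5)
        if not contours:
            continue
        contour = max(contours, key=len)
        if len(contour) < params.min_contour_points:
            continue
        pts = np.column_stack([contour[:, 1] + c0 - 1, contour[:, 0] + r0 - 1])  # (x, y)
        fit = _fit_ellipse_lsq(pts)
        if fit is None:
            cy, cx = region.centroid
            fit = ((cx, cy), region.axis_major_length, max(region.axis_minor_length, 1e-6),
                   float(np.degrees(region.orientation) % 180.0))
        center, major, minor, angle = fit
        area = np.pi * major * minor / 4.0
        ecc = np.sqrt(max(1.0 - (minor / max(major, 1e-12)) ** 2, 0.0))
        if not (params.min_area_px2 <= area <= max_area):
            continue
        if ecc > params.max_eccentricity:
            continue
        if not (0 <= center[0] < w and 0 <= center[1] < h):
            continue
        detections.append(EllipseDetection(
            slice_index=slice_index, center=center, major_axis=major,
            minor_axis=minor, angle=angle, source=source))
    # overlapping duplicates: keep the larger
    detections.sort(key=lambda d: -d.area)
    kept: list[EllipseDetection] = []
    for d in detections:
        if all(np.hypot(d.center[0] - k.center[0], d.center[1] - k.center[1])
               > 0.5 * min(d.major_axis, k.major_axis) for k in kept):
            kept.append(d)
    return kept


@runtime_checkable
class MaskBackend(Protocol):
    """Promptable-mask contract: image + point prompts → one mask per prompt."""

    def __call__(self, image: np.ndarray, points: Sequence[tuple[float, float]]
                 ) -> list[np.ndarray]: ...


class ThresholdFloodBackend:
    """Built-in promptable segmenter: Otsu threshold + connected component at the prompt.

    Returns an all-false mask for prompts that do not land on a
    foreground (above-threshold) pixel.
    """

    def __call__(self, image: np.ndarray, points: Sequence[tuple[float, float]]
                 ) -> list[np.ndarray]:
        img = np.asarray(image, dtype=np.float64)
        if img.max() == img.min():
            return [np.zeros(img.shape, bool) for _ in points]
        thr = threshold_otsu(img)
        fg = img > thr
        labels = measure.label(fg)
        masks = []
        for x, y in points:
            r, c = int(round(y)), int(round(x))
            if not (0 <= r < img.shape[0] and 0 <= c < img.shape[1]) or labels[r, c] == 0:
                masks.append(np.zeros(img.shape, bool))
            else:
                masks.append(labels == labels[r, c])
        return masks


def segment_with_backend(
    image: np.ndarray,
    point_prompts: Sequence[tuple[float, float]],
    backend: MaskBackend | None = None,
) -> list[np.ndarray]:
    """Segment one mask per point prompt through a promptable-mask backend.

    Masks that do not contain their own prompt are discarded (the standard
    filter for zero-shot promptable segmenters, which may return unrelated
    objects).  If the supplied backend raises, the built-in
    :class:`ThresholdFloodBackend` is used instead with a logged warning.
    """
    builtin = ThresholdFloodBackend()
    if backend is None:
        backend = builtin
    try:
        masks = backend(image, point_prompts)
    except Exception as exc:  # pragma: no cover - exercised via fake failing backend
        logger.warning("mask backend %r failed (%s); falling back to built-in "
                       "threshold/flood backend", backend, exc)
        masks = builtin(image, point_prompts)
    kept = []
    for (x, y), mask in zip(point_prompts, masks):
        mask = np.asarray(mask, dtype=bool)
        r, c = int(round(y)), int(round(x))
        if 0 <= r < mask.shape[0] and 0 <= c < mask.shape[1] and mask[r, c]:
            kept.append(mask)
    return kept


def mask_to_ellipse(mask: np.ndarray, slice_index: int, source: str = "backend") -> EllipseDetection:
    """Moment-based ellipse of a binary mask; width is the major axis."""
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n < 5:
        raise ValueError(f"mask has {n} foreground pixels; at least 5 required for an ellipse fit")
    labels = measure.label(mask)
    regions = measure.regionprops(labels)
    region = max(regions, key=lambda r: r.area)
    cy, cx = region.centroid
    major = float(region.axis_major_length)
    minor = float(max(region.axis_minor_length, 1e-6))
    # skimage orientation: angle of major axis from the row (y) axis
    angle = float((90.0 - np.degrees(region.orientation)) % 180.0)
    return EllipseDetection(slice_index=slice_index, center=(float(cx), float(cy)),
                            major_axis=major, minor_axis=minor, angle=angle, source=source)
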