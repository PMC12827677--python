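"""Marker extraction from the 2D section image and cone assignment.

The stained section shows the three cone cross-sections as saturated
elliptical profiles.  After a marker-emphasis preprocessing step (channel
selection and a saturation threshold, since stain appearance varies with
microscope settings), the same rule-based chain used on CT slices extracts
candidate ellipses; each is then assigned to its cone from the approximate
relative marker layout.  The *major* axis of each histology ellipse is the
width used for the height lookup: an oblique cut lengthens only the major
axis, so the major axis is the measurement comparable to the CT width at
the cut height.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detect import DetectionParams, EllipseDetection, detect_ellipses_slice
from .matching import AmbiguousMatchError, match_positions

__all__ = ["SectionMarkers", "HistologyPreprocess", "detect_section_ellipses",
           "match_to_cones", "major_axis_mm"]


class TooFewMarkersError(ValueError):
    pass


@dataclass(frozen=True)
class HistologyPreprocess:
    """Marker-emphasis preprocessing ahead of the detection chain.

    ``channel``: for RGB input, ``"auto"`` picks the channel with the
    largest dynamic range, an int picks one, ``"gray"`` averages.
    ``saturation_threshold``: fraction of the dynamic range below which
    pixels are suppressed (markers are the most saturated structures);
    ``invert`` for dark-marker stains.
    """

    channel: int | str = "auto"
    saturation_threshold: float = 0.75
    invert: bool = False


def _to_marker_gray(image: np.ndarray, prep: HistologyPreprocess) -> np.ndarray:
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 3:
        if prep.channel == "gray":
            img = img.mean(axis=2)
        elif prep.channel == "auto":
            spans = [img[..., c].max() - img[..., c].min() for c in range(img.shape[2])]
            img = img[..., int(np.argmax(spans))]
        else:
            img = img[..., int(prep.channel)]
    if prep.invert:
        img = img.max() - img
    lo, hi = img.min(), img.max()
    if hi > lo:
        norm = (img - lo) / (hi - lo)
        img = np.where(norm >= prep.saturation_threshold, norm, 0.0)
    return img


def detect_section_ellipses(
    image: np.ndarray,
    params: DetectionParams = DetectionParams(),
    preprocess: HistologyPreprocess = HistologyPreprocess(),
    n_expected: int = 3,
) -> list[EllipseDetection]:
    """Extract candidate marker ellipses from the section image.

    Raises :class:`TooFewMarkersError` when fewer than ``n_expected``
    candidates survive the chain (e.g. a blank image, or tissue-only
    structures removed by the saturation/eccentricity/size filters).
    """
    gray = _to_marker_gray(image, preprocess)
    if gray.max() == gray.min():
        raise TooFewMarkersError(
            f"0 marker candidates found ({n_expected} expected): image has no "
            "structure after marker-emphasis preprocessing")
    ellipses = detect_ellipses_slice(gray, params, slice_index=0, source="histology")
    if len(ellipses) < n_expected:
        raise TooFewMarkersError(
            f"only {len(ellipses)} marker candidates found, {n_expected} expected; "
            "adjust detection/preprocessing parameters")
    return ellipses


@dataclass
class SectionMarkers:
    """Section ellipses with their cone assignment."""

    ellipses: list[EllipseDetection]
    pixel_size: float                              # mm per section pixel
    assignment: dict[str, EllipseDetection] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    def widths_mm(self) -> dict[str, float]:
        return {cid: e.major_axis * self.pixel_size for cid, e in self.assignment.items()}


def match_to_cones(
    section_ellipses: list[EllipseDetection],
    expected_layout: dict[str, tuple[float, float]],
    pixel_size: float,
    ambiguity_margin: float = 1e-3,
) -> SectionMarkers:
    """Assign each cone its section ellipse from the approximate relative layout.

    Assignment minimizes total normalized squared distance between ellipse
    centers and layout positions (translation- and scale-invariant; see
    :func:`conefuse.matching.match_positions`).  Surplus ellipses stay
    unassigned; ambiguous layouts raise rather than guess.
    """
    centers = np.array([e.center for e in section_ellipses], dtype=float)
    idx = match_positions(centers, expected_layout, ambiguity_margin=ambiguity_margin)
    assignment = {cid: section_ellipses[i] for cid, i in idx.items()}
    return SectionMarkers(ellipses=list(section_ellipses), pixel_size=pixel_size,
                          assignment=assignment)


def major_axis_mm(ellipse: EllipseDetection, pixel_size: float) -> float:
    """Major axis of a fitted ellipse converted to mm."""
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    return ellipse.major_axis * pixel_size
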