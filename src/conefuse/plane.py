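"""Cutting-plane geometry: three-point plane embedding and oblique slice extraction.

A physical section is located inside the CT volume from three marker
correspondences: each cone contributes one 2D point (the ellipse center in
section coordinates, mm) and one 3D point (the cone axis at the height
decoded from the taper calibration, mm).  Three such pairs determine a
unique affine map A from section coordinates into volume coordinates; its
image is the cutting plane, and sampling the volume along A with trilinear
interpolation yields the in-silico plane used for registration.

Coordinate conventions are defined in :mod:`conefuse.volume`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping

import numpy as np
from scipy.ndimage import map_coordinates

from .volume import VoxelVolume

if TYPE_CHECKING:  # pragma: no cover
    from .calibrate import TaperModel
    from .histology import SectionMarkers


class CollinearPointsError(ValueError):
    """Raised when the three correspondences do not define a plane."""


@dataclass
class PlaneEmbedding:
    """Affine map from 2D section coordinates (mm) into 3D volume coordinates (mm).

    ``map(p) = origin + p[0] * basis_u + p[1] * basis_v`` for a 2D point
    ``p = (u, v)`` in mm.  ``normal`` is the unit normal of the plane.
    """

    origin: np.ndarray          # (3,) mm, image of (0, 0)
    basis_u: np.ndarray         # (3,) mm per section-mm along u
    basis_v: np.ndarray         # (3,) mm per section-mm along v
    points_2d: np.ndarray | None = field(default=None)   # (n, 2) source correspondences
    points_3d: np.ndarray | None = field(default=None)   # (n, 3)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.basis_u = np.asarray(self.basis_u, dtype=float).reshape(3)
        self.basis_v = np.asarray(self.basis_v, dtype=float).reshape(3)
        if np.linalg.norm(np.cross(self.basis_u, self.basis_v)) < 1e-12:
            raise CollinearPointsError("basis vectors are linearly dependent")

    @property
    def normal(self) -> np.ndarray:
        n = np.cross(self.basis_u, self.basis_v)
        return n / np.linalg.norm(n)

    def map_points(self, uv: np.ndarray) -> np.ndarray:
        """Map an (n, 2) array of section points (mm) to (n, 3) volume points (mm)."""
        uv = np.atleast_2d(np.asarray(uv, dtype=float))
        return self.origin + uv[:, :1] * self.basis_u + uv[:, 1:2] * self.basis_v

    def signed_distance(self, points_3d: np.ndarray) -> np.ndarray:
        """Signed distance (mm) of 3D points from the plane."""
        pts = np.atleast_2d(np.asarray(points_3d, dtype=float))
        return (pts - self.origin) @ self.normal

    def to_dict(self) -> dict:
        d = {
            "origin_mm": self.origin.tolist(),
            "basis_u_mm": self.basis_u.tolist(),
            "basis_v_mm": self.basis_v.tolist(),
            "normal": self.normal.tolist(),
        }
        if self.points_2d is not None:
            d["points_2d_mm"] = np.asarray(self.points_2d).tolist()
        if self.points_3d is not None:
            d["points_3d_mm"] = np.asarray(self.points_3d).tolist()
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PlaneEmbedding":
        return cls(
            origin=np.array(d["origin_mm"]),
            basis_u=np.array(d["basis_u_mm"]),
            basis_v=np.array(d["basis_v_mm"]),
            points_2d=np.array(d["points_2d_mm"]) if "points_2d_mm" in d else None,
            points_3d=np.array(d["points_3d_mm"]) if "points_3d_mm" in d else None,
        )


def build_embedding(section_points_2d: np.ndarray, volume_points_3d: np.ndarray) -> PlaneEmbedding:
    """Solve the unique affine 2D→3D map through three point correspondences.

    Parameters
    ----------
    section_points_2d:
        (3, 2) points in section coordinates, mm.
    volume_points_3d:
        (3, 3) matching points in volume coordinates, mm.

    Raises
    ------
    CollinearPointsError
        If either point triple is (numerically) collinear.
    """
    p = np.asarray(section_points_2d, dtype=float).reshape(3, 2)
    P = np.asarray(volume_points_3d, dtype=float).reshape(3, 3)

    d2 = np.column_stack([p[1] - p[0], p[2] - p[0]])       # 2x2
    scale2 = max(np.abs(d2).max(), 1e-300)
    if abs(np.linalg.det(d2)) < 1e-9 * scale2**2:
        raise CollinearPointsError("2D section points are collinear")
    D3 = np.column_stack([P[1] - P[0], P[2] - P[0]])       # 3x2
    if np.linalg.norm(np.cross(D3[:, 0], D3[:, 1])) < 1e-9 * max(np.abs(D3).max(), 1e-300) ** 2:
        raise CollinearPointsError("3D volume points are collinear")

    B = D3 @ np.linalg.inv(d2)                             # 3x2 linear part
    origin = P[0] - B @ p[0]
    emb = PlaneEmbedding(origin=origin, basis_u=B[:, 0], basis_v=B[:, 1],
                         points_2d=p.copy(), points_3d=P.copy())
    # exact-interpolation self check
    resid = np.abs(emb.map_points(p) - P).max()
    if resid > 1e-6:
        raise CollinearPointsError(f"embedding failed to reproduce correspondences (resid {resid:.3g} mm)")
    return emb


def locate_cone_points(
    markers: "SectionMarkers",
    tapers: Mapping[str, "TaperModel"],
    voxel_size: float,
) -> dict[str, np.ndarray]:
    """Convert matched section ellipses into 3D volume points via the taper calibration.

    For each cone assigned in ``markers``: the measured major axis (mm) is
    inverted through that cone's taper regression to a continuous slice
    index z; the cone axis position (x, y) at z comes from the calibrated
    center-drift model.  Returns ``{cone_id: (x, y, z) mm}``.
    """
    points: dict[str, np.ndarray] = {}
    for cone_id, ellipse in markers.assignment.items():
        if cone_id not in tapers:
            raise KeyError(f"no taper model for assigned cone {cone_id!r}")
        model = tapers[cone_id]
        width_mm = ellipse.major_axis * markers.pixel_size
        z_index = model.z_at(width_mm, warn_extrapolation=True)
        cx_px, cy_px = model.center_at(z_index)
        points[cone_id] = np.array([cx_px * voxel_size, cy_px * voxel_size, z_index * voxel_size])
    return points


def section_points_mm(markers: "SectionMarkers") -> dict[str, np.ndarray]:
    """Ellipse centers of the assigned cones in section coordinates (mm)."""
    return {
        cone_id: np.array([e.center[0] * markers.pixel_size, e.center[1] * markers.pixel_size])
        for cone_id, e in markers.assignment.items()
    }


def embedding_from_markers(
    markers: "SectionMarkers",
    tapers: Mapping[str, "TaperModel"],
    voxel_size: float,
) -> PlaneEmbedding:
    """Convenience wrapper: locate the three cone points and build the embedding."""
    pts3 = locate_cone_points(markers, tapers, voxel_size)
    pts2 = section_points_mm(markers)
    cone_ids = sorted(pts3)
    return build_embedding(
        np.array([pts2[c] for c in cone_ids]),
        np.array([pts3[c] for c in cone_ids]),
    )


def extract_oblique_slice(
    volume: VoxelVolume,
    embedding: PlaneEmbedding,
    out_shape: tuple[int, int],
    pixel_pitch: float | None = None,
    fill_value: float = 0.0,
) -> np.ndarray:
    """Sample the volume along the embedded plane with trilinear interpolation.

    Output pixel (row v, col u) is sampled at ``embedding.map((u*s, v*s))``
    where ``s`` is ``pixel_pitch`` (defaults to the volume voxel size, i.e.
    the section is resampled at CT scale).  Sample points outside the volume
    take ``fill_value``.
    """
    if pixel_pitch is None:
        pixel_pitch = volume.voxel_size
    h, w = out_shape
    if h <= 0 or w <= 0:
        raise ValueError(f"out_shape must be positive, got {out_shape}")
    vv, uu = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
    s = float(pixel_pitch)
    pts = (
        embedding.origin[:, None, None]
        + (uu * s) * embedding.basis_u[:, None, None]
        + (vv * s) * embedding.basis_v[:, None, None]
    )  # (3, h, w) as (x, y, z) mm
    coords = pts[::-1] / volume.voxel_size  # (z, y, x) voxel indices
    out = map_coordinates(volume.data.astype(np.float64), coords, order=1,
                          mode="constant", cval=float(fill_value))
    return out.astype(np.float32)


def plane_angle_deg(a: PlaneEmbedding, b: PlaneEmbedding) -> float:
    """Angle in degrees between two plane normals (orientation-agnostic)."""
    c = abs(float(np.dot(a.normal, b.normal)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def mean_plane_distance_mm(
    recovered: PlaneEmbedding,
    truth: PlaneEmbedding,
    footprint_uv_mm: np.ndarray,
) -> float:
    """Mean unsigned distance (mm) between planes over a section footprint.

    ``footprint_uv_mm`` are 2D points (mm) in the *recovered* section frame;
    each is mapped to 3D and its distance to the truth plane measured.
    """
    pts = recovered.map_points(footprint_uv_mm)
    return float(np.abs(truth.signed_distance(pts)).mean())
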