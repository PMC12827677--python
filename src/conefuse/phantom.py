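"""Synthetic microCT phantoms with conic reference markers.

Generates 3D volumes that emulate a resin-embedded specimen flanked by
three 3D-printed truncated cones (the reference markers), plus a
tissue-like textured blob, depth-dependent marker attenuation
(sedimentation of the contrast agent during printing) and additive noise.
A ground-truth cutting plane can then be "sectioned" into a simulated
histology image with known marker ellipse parameters, giving every
downstream stage (detection, taper calibration, plane recovery,
registration, scoring) a parameter-recovery test without any real scans.

The default marker geometry is the printed design: height 11 mm, base
diameter 3 mm, apex diameter 0.5 mm, giving the linear taper
``width(h) = 3 - (2.5 / 11) * h`` mm at height ``h`` above the base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, map_coordinates

from .plane import PlaneEmbedding
from .volume import VoxelVolume

__all__ = [
    "ConeSpec",
    "TissueParams",
    "StainParams",
    "PhantomGroundTruth",
    "SectionSample",
    "generate_phantom_volume",
    "sample_section_image",
    "make_cutting_plane",
    "default_three_cone_specs",
    "PRINTED_CONE_HEIGHT_MM",
    "PRINTED_CONE_BASE_DIAMETER_MM",
    "PRINTED_CONE_APEX_DIAMETER_MM",
]

# printed reference-marker design dimensions (mm)
PRINTED_CONE_HEIGHT_MM = 11.0
PRINTED_CONE_BASE_DIAMETER_MM = 3.0
PRINTED_CONE_APEX_DIAMETER_MM = 0.5


class ConeOutsideVolumeError(ValueError):
    pass


class OverlappingConesError(ValueError):
    pass


class PlaneMissesConeError(ValueError):
    pass


@dataclass(frozen=True)
class ConeSpec:
    """A truncated cone marker, axis parallel to z (the stack axis).

    Heights ``h`` are measured in mm upward from the base plane ``base_z``.
    """

    base_center: tuple[float, float]          # (x, y) mm at the base layer
    base_z: float = 0.0                       # mm
    height: float = PRINTED_CONE_HEIGHT_MM      # mm
    base_diameter: float = PRINTED_CONE_BASE_DIAMETER_MM
    apex_diameter: float = PRINTED_CONE_APEX_DIAMETER_MM
    attenuation: float = 1.0                  # intensity above zero level
    sedimentation_slope: float = 0.0          # intensity per mm of height

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ValueError("cone height must be > 0")
        if not self.base_diameter > self.apex_diameter > 0:
            raise ValueError("need base_diameter > apex_diameter > 0")

    @property
    def taper_mm_per_mm(self) -> float:
        """Width decrease per mm of height: (base - apex) / height."""
        return (self.base_diameter - self.apex_diameter) / self.height

    def width_at(self, h: float | np.ndarray) -> np.ndarray:
        """Cross-section diameter (mm) at height ``h`` above the base."""
        return self.base_diameter - self.taper_mm_per_mm * np.asarray(h, dtype=float)

    def radius_at(self, h: float | np.ndarray) -> np.ndarray:
        return 0.5 * self.width_at(h)

    def contains(self, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
        """Vectorized solid test for physical points (mm)."""
        h = np.asarray(z, dtype=float) - self.base_z
        in_z = (h >= 0) & (h <= self.height)
        r = self.radius_at(np.clip(h, 0, self.height))
        d2 = (np.asarray(x) - self.base_center[0]) ** 2 + (np.asarray(y) - self.base_center[1]) ** 2
        return in_z & (d2 <= r**2)


@dataclass(frozen=True)
class TissueParams:
    """Band-limited textured blob standing in for the embedded biopsy.

    The texture is a Gaussian-smoothed white-noise field; voxels of the
    blob (a vertical cylinder between the cones) whose field value exceeds
    the ``fill_quantile`` carry intensity between the embedding medium and
    the marker attenuation, scaled by ``amplitude``.
    """

    center_xy_mm: tuple[float, float] | None = None   # None → volume center
    radius_mm: float = 1.8
    z_range_mm: tuple[float, float] | None = None      # None → full stack
    amplitude: float = 0.5                             # intensity span above medium
    granularity_mm: float = 0.3                        # smoothing sigma of the field
    fill_quantile: float = 0.35                        # fraction of cylinder left empty


@dataclass(frozen=True)
class StainParams:
    """Rendering of the simulated histology section.

    Markers are flat-shaded at ``marker_value``.  Tissue re-uses the CT
    texture sampled on the plane but passes it through a monotone stain
    transfer (optional inversion + gamma) into ``[tissue_low, tissue_high]``
    — same structure, different contrast, as a stained section of the same
    block would show.
    """

    marker_value: float = 1.0
    tissue_low: float = 0.25
    tissue_high: float = 0.65
    background: float = 0.05
    invert_tissue: bool = True
    gamma: float = 1.2
    blur_sigma_px: float = 0.0
    noise_sigma: float = 0.0


@dataclass
class PhantomGroundTruth:
    """Everything the generator knows, for parameter-recovery tests."""

    cone_specs: dict[str, ConeSpec]
    voxel_size: float
    shape: tuple[int, int, int]
    medium_value: float
    noise_sigma: float
    tissue: TissueParams | None = None
    plane: PlaneEmbedding | None = None

    def center_px(self, cone_id: str) -> tuple[float, float]:
        cx, cy = self.cone_specs[cone_id].base_center
        return (cx / self.voxel_size, cy / self.voxel_size)

    def slice_range(self, cone_id: str) -> tuple[int, int]:
        """Inclusive z-index range of slices intersecting the cone."""
        c = self.cone_specs[cone_id]
        lo = int(np.ceil(c.base_z / self.voxel_size - 1e-9))
        hi = int(np.floor((c.base_z + c.height) / self.voxel_size + 1e-9))
        return (max(lo, 0), min(hi, self.shape[0] - 1))

    def true_width_mm(self, cone_id: str, z_index: float | np.ndarray) -> np.ndarray:
        c = self.cone_specs[cone_id]
        return c.width_at(np.asarray(z_index, dtype=float) * self.voxel_size - c.base_z)

    def true_taper_slope_mm_per_slice(self, cone_id: str) -> float:
        """Analytic width-vs-slice-index slope (negative: width shrinks upward)."""
        return -self.cone_specs[cone_id].taper_mm_per_mm * self.voxel_size

    def per_slice_truth(self) -> pd.DataFrame:
        rows = []
        for cid in self.cone_specs:
            lo, hi = self.slice_range(cid)
            ks = np.arange(lo, hi + 1)
            w = self.true_width_mm(cid, ks)
            cx, cy = self.center_px(cid)
            for k, wk in zip(ks, w):
                rows.append({"cone_id": cid, "slice": int(k), "width_mm": float(wk),
                             "width_px": float(wk / self.voxel_size), "cx_px": cx, "cy_px": cy})
        return pd.DataFrame(rows)

    def expected_layout(self) -> dict[str, tuple[float, float]]:
        """Relative (x, y) marker layout for section-to-cone matching."""
        return {cid: spec.base_center for cid, spec in self.cone_specs.items()}


def default_three_cone_specs(
    shape: tuple[int, int, int] = (256, 256, 256),
    voxel_size: float = 0.05,
    attenuation: float = 1.0,
    sedimentation_slope: float = 0.0,
    base_z: float = 0.5,
) -> dict[str, ConeSpec]:
    """Three printed-design cones in an asymmetric triangle inside the volume."""
    nz, ny, nx = shape
    xe, ye = (nx - 1) * voxel_size, (ny - 1) * voxel_size
    fractions = {"cone_0": (0.25, 0.25), "cone_1": (0.75, 0.30), "cone_2": (0.50, 0.75)}
    return {
        cid: ConeSpec(
            base_center=(fx * xe, fy * ye),
            base_z=base_z,
            attenuation=attenuation,
            sedimentation_slope=sedimentation_slope,
        )
        for cid, (fx, fy) in fractions.items()
    }


def _check_geometry(specs: dict[str, ConeSpec], shape, voxel_size) -> None:
    nz, ny, nx = shape
    xe, ye, ze = (nx - 1) * voxel_size, (ny - 1) * voxel_size, (nz - 1) * voxel_size
    for cid, c in specs.items():
        r = c.base_diameter / 2
        cx, cy = c.base_center
        if cx - r < 0 or cx + r > xe or cy - r < 0 or cy + r > ye or c.base_z < 0 or c.base_z + c.height > ze:
            raise ConeOutsideVolumeError(
                f"cone {cid!r} extends outside the volume "
                f"(center {c.base_center} mm, base radius {r} mm, z [{c.base_z}, {c.base_z + c.height}] mm; "
                f"volume extent ({xe:.3g}, {ye:.3g}, {ze:.3g}) mm)"
            )
    ids = list(specs)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            ca, cb = specs[a], specs[b]
            lo = max(ca.base_z, cb.base_z)
            hi = min(ca.base_z + ca.height, cb.base_z + cb.height)
            if hi < lo:
                continue
            # radii are widest at the lowest shared height
            rsum = float(ca.radius_at(lo - ca.base_z) + cb.radius_at(lo - cb.base_z))
            dist = float(np.hypot(ca.base_center[0] - cb.base_center[0],
                                  ca.base_center[1] - cb.base_center[1]))
            if dist < rsum:
                raise OverlappingConesError(f"cones {a!r} and {b!r} overlap (centers {dist:.3g} mm apart)")


def generate_phantom_volume(
    cone_specs: dict[str, ConeSpec] | Sequence[ConeSpec] | None = None,
    shape: tuple[int, int, int] = (256, 256, 256),
    voxel_size: float = 0.05,
    medium_value: float = 0.1,
    tissue_params: TissueParams | None = TissueParams(),
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[VoxelVolume, PhantomGroundTruth]:
    """Render the marker + tissue phantom and its ground-truth record.

    Parameters
    ----------
    cone_specs:
        Markers to embed; ``None`` uses :func:`default_three_cone_specs`.
        A sequence is assigned ids ``cone_0`` … in order.
    shape:
        Volume shape ``(nz, ny, nx)``.
    voxel_size:
        Isotropic voxel size in mm.
    medium_value:
        Intensity of the embedding resin background.
    tissue_params:
        Textured-blob parameters, or ``None`` for no tissue.
    noise_sigma:
        Standard deviation of additive Gaussian noise.
    seed:
        Seeds texture and noise; identical inputs give identical volumes.
    """
    if cone_specs is None:
        cone_specs = default_three_cone_specs(shape, voxel_size)
    if not isinstance(cone_specs, dict):
        cone_specs = {f"cone_{i}": c for i, c in enumerate(cone_specs)}
    if voxel_size <= 0:
        raise ValueError("voxel_size must be > 0")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    _check_geometry(cone_specs, shape, voxel_size)

    nz, ny, nx = shape
    rng = np.random.default_rng(seed)
    vol = np.full(shape, float(medium_value), dtype=np.float64)
    z_mm = np.arange(nz, dtype=float) * voxel_size
    y_mm = np.arange(ny, dtype=float) * voxel_size
    x_mm = np.arange(nx, dtype=float) * voxel_size

    occupancy = np.zeros(shape, dtype=bool)
    for cid, c in cone_specs.items():
        h = z_mm - c.base_z
        in_z = (h >= 0) & (h <= c.height)
        r = np.where(in_z, c.radius_at(np.clip(h, 0, c.height)), -1.0)
        d2 = (x_mm[None, :] - c.base_center[0]) ** 2 + (y_mm[:, None] - c.base_center[1]) ** 2
        inside = d2[None, :, :] <= (r**2)[:, None, None]
        inside &= in_z[:, None, None]
        value = c.attenuation + c.sedimentation_slope * np.clip(h, 0, c.height)
        vol = np.where(inside, value[:, None, None], vol)
        occupancy |= inside

    if tissue_params is not None:
        tp = tissue_params
        cx, cy = tp.center_xy_mm if tp.center_xy_mm is not None else (
            (nx - 1) * voxel_size / 2, (ny - 1) * voxel_size / 2)
        zlo, zhi = tp.z_range_mm if tp.z_range_mm is not None else (0.0, (nz - 1) * voxel_size)
        field_raw = rng.standard_normal(shape)
        field_sm = gaussian_filter(field_raw, sigma=tp.granularity_mm / voxel_size)
        fmin, fmax = field_sm.min(), field_sm.max()
        field01 = (field_sm - fmin) / max(fmax - fmin, 1e-30)
        cyl = ((x_mm[None, :] - cx) ** 2 + (y_mm[:, None] - cy) ** 2 <= tp.radius_mm**2)
        region = cyl[None, :, :] & ((z_mm >= zlo) & (z_mm <= zhi))[:, None, None] & ~occupancy
        thr = np.quantile(field01[region], tp.fill_quantile) if region.any() else 1.0
        blob = region & (field01 > thr)
        tex = (field01 - thr) / max(1.0 - thr, 1e-30)
        vol = np.where(blob, medium_value + tp.amplitude * tex, vol)

    if noise_sigma > 0:
        vol = vol + rng.normal(0.0, noise_sigma, size=shape)

    truth = PhantomGroundTruth(
        cone_specs=dict(cone_specs), voxel_size=voxel_size, shape=tuple(shape),
        medium_value=medium_value, noise_sigma=noise_sigma, tissue=tissue_params,
    )
    return VoxelVolume(vol.astype(np.float32), voxel_size), truth


def make_cutting_plane(
    shape: tuple[int, int, int],
    voxel_size: float,
    z0_mm: float,
    tilt_deg: float = 0.0,
    azimuth_deg: float = 0.0,
    pixel_size: float | None = None,
    fov_mm: tuple[float, float] | None = None,
) -> tuple[PlaneEmbedding, tuple[int, int]]:
    """Build a ground-truth cutting plane through the volume.

    The plane passes through the volume's XY center at height ``z0_mm``
    and is tilted by ``tilt_deg`` about an in-plane axis whose direction is
    set by ``azimuth_deg``.  With ``tilt_deg = 0`` and ``pixel_size`` equal
    to the voxel size, section pixel (u, v) coincides with voxel (x, y) of
    slice ``z0_mm / voxel_size``.

    Returns the embedding (an isometry: unit, orthogonal basis) and the
    output image shape covering ``fov_mm`` (default: the volume XY extent).
    """
    nz, ny, nx = shape
    s = voxel_size if pixel_size is None else float(pixel_size)
    if fov_mm is None:
        fov_mm = ((nx - 1) * voxel_size, (ny - 1) * voxel_size)
    w = int(round(fov_mm[0] / s)) + 1
    h = int(round(fov_mm[1] / s)) + 1

    t, a = np.radians(tilt_deg), np.radians(azimuth_deg)
    rx = np.array([[1, 0, 0], [0, np.cos(t), -np.sin(t)], [0, np.sin(t), np.cos(t)]])
    rz = np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])
    normal = rz @ rx @ np.array([0.0, 0.0, 1.0])
    # in-plane frame stays block-aligned (sections are cut roughly parallel
    # to the stack axes): project x onto the plane, complete right-handed
    e_u = np.array([1.0, 0.0, 0.0]) - normal[0] * normal
    e_u /= np.linalg.norm(e_u)
    e_v = np.cross(normal, e_u)
    center = np.array([(nx - 1) * voxel_size / 2, (ny - 1) * voxel_size / 2, z0_mm])
    origin = center - ((w - 1) / 2 * s) * e_u - ((h - 1) / 2 * s) * e_v
    return PlaneEmbedding(origin=origin, basis_u=e_u, basis_v=e_v), (h, w)


@dataclass
class SectionSample:
    """A simulated histology section plus its ground truth."""

    image: np.ndarray                 # (h, w) float32
    pixel_size: float                 # mm/px
    plane: PlaneEmbedding
    # per cone: dict with center (x, y) px, major/minor axis px, angle deg
    gt_ellipses: dict[str, dict]


def _ellipse_from_moments(u: np.ndarray, v: np.ndarray) -> dict:
    """Uniform-density ellipse parameters from point coordinates (px)."""
    mu = np.array([u.mean(), v.mean()])
    cov = np.cov(np.vstack([u, v]), bias=True)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    major, minor = 4 * np.sqrt(np.maximum(evals, 0))
    angle = float(np.degrees(np.arctan2(evecs[1, 0], evecs[0, 0])) % 180.0)
    return {"center": (float(mu[0]), float(mu[1])), "major_axis": float(major),
            "minor_axis": float(minor), "angle": angle}


def sample_section_image(
    volume: VoxelVolume,
    truth: PhantomGroundTruth,
    plane: PlaneEmbedding,
    pixel_size: float,
    out_shape: tuple[int, int],
    stain: StainParams | None = None,
    seed: int = 0,
    supersample: int = 3,
) -> SectionSample:
    """Render the simulated stained section cut along ``plane``.

    Marker cross-sections come from the analytic cone solids evaluated on
    the section grid (supersampled for the ground-truth ellipse moments);
    tissue intensity is the CT texture sampled on the plane, pushed through
    the stain transfer curve.  Raises :class:`PlaneMissesConeError` listing
    the cones the plane fails to cut.
    """
    if stain is None:
        stain = StainParams()
    rng = np.random.default_rng(seed)
    h, w = out_shape
    s = float(pixel_size)

    vv, uu = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
    pts = (plane.origin[:, None, None] + (uu * s) * plane.basis_u[:, None, None]
           + (vv * s) * plane.basis_v[:, None, None])
    px, py, pz = pts

    image = np.full(out_shape, stain.background, dtype=np.float64)

    # tissue: sample the CT volume on the plane, stain-map monotonically
    if truth.tissue is not None:
        coords = pts[::-1] / volume.voxel_size
        ct_vals = map_coordinates(volume.data.astype(np.float64), coords, order=1,
                                  mode="constant", cval=truth.medium_value)
        amp = truth.tissue.amplitude
        lvl = np.clip((ct_vals - truth.medium_value) / max(amp, 1e-30), 0.0, 1.0)
        tissue_mask = lvl > 0.05
        if stain.invert_tissue:
            lvl = 1.0 - lvl
        lvl = lvl ** stain.gamma
        stained = stain.tissue_low + (stain.tissue_high - stain.tissue_low) * lvl
        image = np.where(tissue_mask, stained, image)

    gt_ellipses: dict[str, dict] = {}
    missed: list[str] = []
    f = max(int(supersample), 1)
    u_fine = (np.arange(w * f) + 0.5) / f - 0.5
    v_fine = (np.arange(h * f) + 0.5) / f - 0.5
    for cid, cone in truth.cone_specs.items():
        inside = cone.contains(px, py, pz)
        if not inside.any():
            missed.append(cid)
            continue
        image = np.where(inside, stain.marker_value, image)
        # ground-truth ellipse from the analytic solid on a finer grid,
        # restricted to the coarse footprint's bounding box for speed
        rows = np.where(inside.any(axis=1))[0]
        cols = np.where(inside.any(axis=0))[0]
        r0, r1 = max(rows[0] - 2, 0), min(rows[-1] + 3, h)
        c0, c1 = max(cols[0] - 2, 0), min(cols[-1] + 3, w)
        uf = u_fine[(u_fine >= c0 - 1) & (u_fine <= c1)]
        vf = v_fine[(v_fine >= r0 - 1) & (v_fine <= r1)]
        VF, UF = np.meshgrid(vf, uf, indexing="ij")
        P = (plane.origin[:, None, None] + (UF * s) * plane.basis_u[:, None, None]
             + (VF * s) * plane.basis_v[:, None, None])
        fine = cone.contains(P[0], P[1], P[2])
        gt_ellipses[cid] = _ellipse_from_moments(UF[fine], VF[fine])
    if missed:
        raise PlaneMissesConeError(
            f"plane does not intersect cones {missed}; cut cones: {sorted(gt_ellipses)}")

    if stain.blur_sigma_px > 0:
        image = gaussian_filter(image, sigma=stain.blur_sigma_px)
    if stain.noise_sigma > 0:
        image = image + rng.normal(0.0, stain.noise_sigma, size=out_shape)

    return SectionSample(image=image.astype(np.float32), pixel_size=s,
                         plane=plane, gt_ellipses=gt_ellipses)
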