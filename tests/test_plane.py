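"""Three-point plane embedding and trilinear oblique-slice extraction."""

import warnings

import numpy as np
import pytest

from conefuse import phantom as ph
from conefuse.plane import (CollinearPointsError, PlaneEmbedding, build_embedding,
                            embedding_from_markers, extract_oblique_slice,
                            mean_plane_distance_mm, plane_angle_deg)
from conefuse.volume import VoxelVolume


class TestBuildEmbedding:
    def test_axis_aligned_case(self):
        p2 = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        p3 = np.array([[0.0, 0.0, 2.0], [1.0, 0.0, 2.0], [0.0, 1.0, 2.0]])
        emb = build_embedding(p2, p3)
        assert abs(emb.normal @ np.array([0.0, 0.0, 1.0])) == pytest.approx(1.0, abs=1e-12)
        assert emb.basis_u == pytest.approx([1.0, 0.0, 0.0])
        assert emb.basis_v == pytest.approx([0.0, 1.0, 0.0])

    def test_rotated_correspondences_recover_normal(self):
        theta = np.radians(17.0)
        rx = np.array([[1, 0, 0],
                       [0, np.cos(theta), -np.sin(theta)],
                       [0, np.sin(theta), np.cos(theta)]])
        p2 = np.array([[0.0, 0.0], [3.0, 0.5], [1.0, 4.0]])
        p3 = np.array([rx @ np.array([u, v, 5.0]) for u, v in p2])
        emb = build_embedding(p2, p3)
        expected_normal = rx @ np.array([0.0, 0.0, 1.0])
        assert abs(emb.normal @ expected_normal) == pytest.approx(1.0, abs=1e-9)

    def test_correspondences_reproduced_exactly(self):
        rng = np.random.default_rng(3)
        p2 = rng.uniform(-5, 5, (3, 2))
        p3 = rng.uniform(-5, 5, (3, 3))
        emb = build_embedding(p2, p3)
        assert np.abs(emb.map_points(p2) - p3).max() < 1e-6

    def test_collinear_points_rejected(self):
        p2 = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        p3 = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 1.0], [0.0, 1.0, 2.0]])
        with pytest.raises(CollinearPointsError):
            build_embedding(p2, p3)
        p2b = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        p3b = np.array([[0.0, 0.0, 0.0], [1.0, 1.0, 1.0], [2.0, 2.0, 2.0]])
        with pytest.raises(CollinearPointsError):
            build_embedding(p2b, p3b)

    def test_normal_orthogonal_to_basis(self):
        rng = np.random.default_rng(4)
        emb = build_embedding(rng.uniform(-2, 2, (3, 2)), rng.uniform(-2, 2, (3, 3)))
        assert abs(emb.normal @ emb.basis_u) < 1e-9
        assert abs(emb.normal @ emb.basis_v) < 1e-9


class TestObliqueExtraction:
    def lattice_volume(self):
        rng = np.random.default_rng(0)
        return VoxelVolume(rng.uniform(0, 1, (20, 30, 30)).astype(np.float32), 1.0)

    def test_integer_slice_identity(self):
        """An axis-aligned plane at integer z returns that slice bit-exactly."""
        vol = self.lattice_volume()
        emb = PlaneEmbedding(origin=np.array([0.0, 0.0, 7.0]),
                             basis_u=np.array([1.0, 0.0, 0.0]),
                             basis_v=np.array([0.0, 1.0, 0.0]))
        out = extract_oblique_slice(vol, emb, (30, 30), pixel_pitch=1.0)
        assert np.array_equal(out, vol.data[7])

    def test_half_slice_on_z_linear_volume(self):
        """Trilinear sampling at z = k + 1/2 averages adjacent slices."""
        vol = self.lattice_volume()
        emb = PlaneEmbedding(origin=np.array([0.0, 0.0, 7.5]),
                             basis_u=np.array([1.0, 0.0, 0.0]),
                             basis_v=np.array([0.0, 1.0, 0.0]))
        out = extract_oblique_slice(vol, emb, (30, 30), pixel_pitch=1.0)
        expected = 0.5 * (vol.data[7] + vol.data[8])
        assert np.abs(out - expected).max() < 1e-6

    def test_trilinear_exact_for_trilinear_field(self):
        """A globally trilinear field is reproduced exactly at arbitrary points."""
        nz, ny, nx = 12, 15, 17
        zz, yy, xx = np.mgrid[0:nz, 0:ny, 0:nx].astype(np.float64)
        field = 0.3 + 0.7 * xx - 0.2 * yy + 1.1 * zz + 0.05 * xx * yy \
            - 0.03 * yy * zz + 0.02 * xx * zz + 0.004 * xx * yy * zz
        vol = VoxelVolume(field, 1.0)
        emb = build_embedding(
            np.array([[0.0, 0.0], [5.0, 0.0], [0.0, 5.0]]),
            np.array([[1.2, 2.3, 3.1], [6.0, 2.9, 4.4], [1.7, 7.7, 5.9]]))
        out = extract_oblique_slice(vol, emb, (8, 8), pixel_pitch=1.0)
        vv, uu = np.mgrid[0:8, 0:8].astype(float)
        pts = emb.map_points(np.column_stack([uu.ravel(), vv.ravel()]))
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
        expected = (0.3 + 0.7 * x - 0.2 * y + 1.1 * z + 0.05 * x * y
                    - 0.03 * y * z + 0.02 * x * z + 0.004 * x * y * z).reshape(8, 8)
        # float32 storage limits agreement
        assert np.abs(out - expected).max() < 1e-3

    def test_out_of_volume_region_filled(self):
        vol = self.lattice_volume()
        emb = PlaneEmbedding(origin=np.array([0.0, 0.0, 18.0]),
                             basis_u=np.array([1.0, 0.0, 0.2]),   # exits the top
                             basis_v=np.array([0.0, 1.0, 0.0]))
        out = extract_oblique_slice(vol, emb, (30, 30), pixel_pitch=1.0, fill_value=-7.0)
        # u * 0.2 + 18 > 19 for u > 5 → fill beyond (1 px interpolation band)
        assert np.all(out[:, 12:] == -7.0)
        assert np.all(out[:, :5] != -7.0)


@pytest.fixture(scope="module")
def recovered(clean_phantom):
    from conefuse.detect import (DetectionParams, detect_ellipses_slice,
                                 params_for_cone_geometry, sample_slice_indices)
    from conefuse.histology import detect_section_ellipses, match_to_cones
    from conefuse.pipeline import calibrate_tracks

    vol, truth = clean_phantom
    params = params_for_cone_geometry(3.0, 0.5, truth.voxel_size)
    dets = []
    for k in sample_slice_indices(vol.n_slices, 60, seed=2):
        dets.extend(detect_ellipses_slice(vol.slice(int(k)), params, slice_index=int(k)))
    tapers = calibrate_tracks(dets, truth.expected_layout(), vol.voxel_size)
    plane_t, shape = ph.make_cutting_plane(truth.shape, truth.voxel_size, z0_mm=5.8,
                                           tilt_deg=3.0, azimuth_deg=25.0,
                                           pixel_size=0.04)
    sec = ph.sample_section_image(vol, truth, plane_t, 0.04, shape, seed=6)
    ellipses = detect_section_ellipses(sec.image, DetectionParams(min_area_px2=100.0),
                                       n_expected=3)
    markers = match_to_cones(ellipses, truth.expected_layout(), 0.04)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        emb = embedding_from_markers(markers, tapers, vol.voxel_size)
    return emb, plane_t, shape, truth, markers, tapers, vol


class TestPlaneRecoveryOnPhantom:
    def test_normal_angle_below_one_degree(self, recovered):
        emb, plane_t, *_ = recovered
        assert plane_angle_deg(emb, plane_t) < 1.0

    def test_mean_plane_distance_below_two_voxels(self, recovered):
        emb, plane_t, shape, truth, *_ = recovered
        h, w = shape
        uv = np.array([[u * 0.04, v * 0.04] for u in np.linspace(0, w - 1, 10)
                       for v in np.linspace(0, h - 1, 10)])
        assert mean_plane_distance_mm(emb, plane_t, uv) < 2 * truth.voxel_size

    def test_in_plane_rotation_equivariance(self, recovered):
        """Rotating the section frame leaves the recovered 3D plane unchanged."""
        emb, plane_t, shape, truth, markers, tapers, vol = recovered
        theta = np.radians(30.0)
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        from conefuse.plane import locate_cone_points, section_points_mm
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            pts3 = locate_cone_points(markers, tapers, vol.voxel_size)
        pts2 = section_points_mm(markers)
        ids = sorted(pts3)
        p2 = np.array([pts2[c] for c in ids]) @ rot.T + np.array([5.0, -2.0])
        emb_rot = build_embedding(p2, np.array([pts3[c] for c in ids]))
        assert plane_angle_deg(emb_rot, emb) < 1e-6
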