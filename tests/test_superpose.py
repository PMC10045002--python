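"""Local frames, bending values, turning points, anchors, initial superposition."""

import numpy as np
import pytest

import sympose as sp
from sympose.errors import (
    CollinearAnchorsError,
    ContourTooShortError,
    DegenerateFrameError,
    NoTurningPointsError,
)
from sympose.superpose import default_k


def square_contour(n_per_side=10, side=10.0, offset=(0.0, 0.0)) -> sp.Contour2D:
    """Closed square, unit-ish spacing, counter-clockwise."""
    s = np.linspace(0.0, side, n_per_side, endpoint=False)
    pts = np.concatenate([
        np.column_stack([s, np.zeros_like(s)]),
        np.column_stack([np.full_like(s, side), s]),
        np.column_stack([side - s, np.full_like(s, side)]),
        np.column_stack([np.zeros_like(s), side - s]),
    ]) + offset
    return sp.Contour2D(pts, closed=True, raster_cell=side / n_per_side)


class TestLocalFrame:
    def test_axes_orthonormal_right_handed(self, phantom_frame):
        f = phantom_frame
        g = np.column_stack([f.normal, f.axis_y, f.axis_z])
        assert np.allclose(g.T @ g, np.eye(3), atol=1e-9)
        assert np.linalg.det(g) == pytest.approx(1.0, abs=1e-9)

    def test_elongated_box_recovers_construction_axes(self):
        rng = np.random.default_rng(0)
        # box elongated along y, flattest along z; symmetric about x = 0
        pts = rng.uniform(-1, 1, (4000, 3)) * [4.0, 10.0, 1.5]
        mesh = sp.TriangleMesh(pts, np.zeros((0, 3), dtype=int))
        f = sp.local_frame(mesh, sp.Plane((1, 0, 0), 0.0))
        assert np.degrees(np.arccos(abs(f.axis_z @ np.array([0, 0, 1.0])))) <= 2.0
        assert np.degrees(np.arccos(abs(f.axis_y @ np.array([0, 1.0, 0])))) <= 2.0

    def test_equivariance_under_moderate_rotation(self, phantom, phantom_mesh):
        q = sp.RigidTransform.from_axis_angle((0.2, 0.3, 1.0), 12.0,
                                              center=phantom_mesh.centroid)
        f0 = sp.local_frame(phantom_mesh, phantom.true_plane)
        f1 = sp.local_frame(phantom_mesh.transformed(q),
                            phantom.true_plane.transformed(q))
        for a0, a1 in ((f0.axis_y, f1.axis_y), (f0.axis_z, f1.axis_z)):
            ang = np.degrees(np.arccos(np.clip(abs((q.rotation @ a0) @ a1), 0, 1)))
            assert ang <= 2.0

    def test_degenerate_when_third_axis_parallel_to_normal(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(-1, 1, (2000, 3)) * [0.3, 8.0, 6.0]  # flattest along x
        mesh = sp.TriangleMesh(pts, np.zeros((0, 3), dtype=int))
        with pytest.raises(DegenerateFrameError):
            sp.local_frame(mesh, sp.Plane((1, 0, 0), 0.0))


class TestBendingValues:
    def test_collinear_points_score_exactly_one(self):
        c = square_contour(n_per_side=12, side=12.0)
        bv = sp.bending_values(c, k=2)
        # interior of an edge: indices 4..7 are mid-edge, collinear both sides
        assert bv[5] == pytest.approx(1.0, abs=1e-12)

    def test_square_corner_with_k2_is_sqrt2(self):
        c = square_contour(n_per_side=10, side=10.0)
        bv = sp.bending_values(c, k=2)
        corners = [0, 10, 20, 30]
        for i in corners:
            assert bv[i] == pytest.approx(np.sqrt(2.0), abs=1e-12)

    def test_hairpin_fold_exceeds_ten(self):
        out = np.column_stack([np.arange(11) * 0.1, np.zeros(11)])
        back = np.column_stack([np.arange(9, 0, -1) * 0.1, np.full(9, 0.004)])
        c = sp.Contour2D(np.vstack([out, back]), closed=True, raster_cell=0.1)
        bv = sp.bending_values(c, k=2)
        fold = int(np.argmax([np.allclose(p, [1.0, 0.0]) for p in c.points]))
        assert bv[fold] > 10.0

    def test_bv_at_least_one_everywhere(self, phantom_contour):
        bv = sp.bending_values(phantom_contour, k=4)
        assert np.all(bv >= 1.0 - 1e-12)

    def test_contour_too_short_for_k(self):
        c = sp.Contour2D(np.array([[0, 0], [1, 0], [0, 1]], float), raster_cell=1.0)
        with pytest.raises(ContourTooShortError):
            sp.bending_values(c, k=2)


class TestTurningPoints:
    def test_square_corners_inside_band_detected(self):
        # square spanning y in [0, 10]: gamma=0.4 band covers y <= 4, i.e.
        # exactly the two corners on the y=0 edge
        c = square_contour(n_per_side=10, side=10.0)
        tp = sp.turning_points(c, k=2, gamma=0.4, threshold=1.2)
        assert len(tp) == 2
        assert np.allclose(sorted(tp.points[:, 0].tolist()), [0.0, 0.0])

    def test_circle_has_no_turning_points(self):
        t = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        c = sp.Contour2D(np.column_stack([10 * np.cos(t), 10 * np.sin(t)]),
                         raster_cell=0.3)
        with pytest.raises(NoTurningPointsError):
            sp.turning_points(c, k=3, gamma=1.0, threshold=1.2)

    def test_threshold_one_returns_all_band_maxima(self):
        c = square_contour(n_per_side=10, side=10.0)
        tp_low = sp.turning_points(c, k=2, gamma=1.0, threshold=1.0)
        tp_high = sp.turning_points(c, k=2, gamma=1.0, threshold=1.2)
        assert set(tp_high.indices) <= set(tp_low.indices)
        assert len(tp_low) == 4  # all four corners are strict local maxima

    def test_scaled_threshold_mode_multiplies_by_k(self):
        c = square_contour(n_per_side=10, side=10.0)
        with pytest.raises(NoTurningPointsError):
            # 1.8 * k = 3.6 exceeds any square-corner bending value
            sp.turning_points(c, k=2, gamma=1.0, threshold=1.8,
                              threshold_mode="scaled_by_k")

    def test_default_k_scales_with_contour_length(self):
        assert default_k(40) == 3
        assert default_k(200) == 10


class TestAnchors:
    def test_p2_matches_voxel_centroid_projection(self, phantom, phantom_mesh,
                                                  phantom_frame, phantom_contour):
        tp = sp.turning_points(phantom_contour)
        anchors = sp.anchor_triple(phantom_mesh, phantom.true_plane, tp, phantom_frame)
        voxel_centroid = phantom.volume.occupied_centers().mean(axis=0)
        expected = voxel_centroid - (phantom.true_plane.signed_distance(
            voxel_centroid)) * phantom.true_plane.normal
        # P2 is the centroid of the surface point cloud, which weights the
        # surface-rich posterior elements more than the solid does: the two
        # centroids agree to a couple of voxels, not exactly
        assert np.linalg.norm(anchors.P2 - expected) <= 1.0

    def test_single_turning_point_is_p1(self, phantom, phantom_mesh,
                                        phantom_frame, phantom_contour):
        tp = sp.turning_points(phantom_contour)
        assert len(tp) == 1
        anchors = sp.anchor_triple(phantom_mesh, phantom.true_plane, tp, phantom_frame)
        expected = phantom_frame.embed(tp.points[0])[0]
        assert np.allclose(anchors.P1, expected, atol=1e-9)

    def test_anchors_transform_with_the_mesh(self, phantom, phantom_mesh):
        q = sp.RigidTransform.from_axis_angle((0, 1, 0.4), 9.0,
                                              center=phantom_mesh.centroid)
        plane_q = phantom.true_plane.transformed(q)
        mesh_q = phantom_mesh.transformed(q)

        def get_anchors(mesh, plane):
            frame = sp.local_frame(mesh, plane)
            c = sp.trace_contour(sp.project_to_plane(mesh, frame), 0.5)
            return sp.anchor_triple(mesh, plane, sp.turning_points(c), frame)

        a0, a1 = get_anchors(phantom_mesh, phantom.true_plane), get_anchors(mesh_q, plane_q)
        for p0, p1 in ((a0.P1, a1.P1), (a0.P2, a1.P2)):
            assert np.linalg.norm(q.apply(p0) - p1) <= 1.0  # raster tolerance


class TestAnchorFrameTransform:
    def canonical(self) -> sp.AnchorTriple:
        return sp.AnchorTriple((0, 0, 0), (1, 0, 0), (0, 1, 0))

    def test_canonical_anchors_give_identity(self):
        t = sp.anchor_frame_transform(self.canonical())
        assert t.is_close(sp.RigidTransform.identity(), atol=1e-12)

    def test_p1_maps_to_origin(self):
        anchors = sp.AnchorTriple((3, 1, -2), (5, 2, 0), (2, 4, -1))
        t = sp.anchor_frame_transform(anchors)
        assert np.allclose(t.apply(anchors.P1), (0, 0, 0), atol=1e-9)

    def test_equivariance_identity(self):
        anchors = sp.AnchorTriple((3, 1, -2), (5, 2, 0), (2, 4, -1))
        x = sp.RigidTransform.from_axis_angle((1, 2, 0), 25.0) \
            @ sp.RigidTransform.from_translation((4, -1, 2))
        moved = sp.AnchorTriple(x.apply(anchors.P1), x.apply(anchors.P2),
                                x.apply(anchors.P3))
        t_old = sp.anchor_frame_transform(anchors)
        t_new = sp.anchor_frame_transform(moved)
        assert t_new.is_close(t_old @ x.inverse(), atol=1e-9)

    def test_collinear_anchors_rejected(self):
        with pytest.raises(CollinearAnchorsError):
            sp.anchor_frame_transform(sp.AnchorTriple((0, 0, 0), (1, 0, 0), (2, 0, 0)))


class TestInitialSuperposition:
    def test_identity_case(self, phantom, phantom_mesh):
        res = sp.initial_superposition(phantom_mesh, phantom.true_plane,
                                       phantom_mesh, phantom.true_plane)
        assert res.transform.rotation_angle_deg() <= 1e-6
        assert np.linalg.norm(res.transform.translation) <= 1e-6

    def test_recovers_known_rigid_copy(self, phantom, phantom_mesh):
        q = sp.RigidTransform.from_axis_angle((0.3, 0.2, 1.0), 9.0,
                                              center=phantom_mesh.centroid) \
            @ sp.RigidTransform.from_translation((2.0, -3.0, 1.0))
        res = sp.initial_superposition(
            phantom_mesh, phantom.true_plane,
            phantom_mesh.transformed(q), phantom.true_plane.transformed(q))
        err = res.transform @ q  # should be identity
        assert err.rotation_angle_deg() <= np.degrees(1e-3)
        c = phantom_mesh.centroid
        assert np.linalg.norm(err.apply(c) - c) <= 0.5

    def test_posterior_deletion_keeps_body_centroids_close(self, phantom, phantom_mesh):
        from dataclasses import replace

        cut = sp.make_phantom(replace(phantom.spec, lamina_removal_fraction=0.2))
        mesh_b = sp.extract_mesh(cut.volume)
        res = sp.initial_superposition(phantom_mesh, phantom.true_plane,
                                       mesh_b, cut.true_plane)
        moved_body = res.transform.apply(cut.body_points())
        d = np.linalg.norm(moved_body.mean(axis=0) - phantom.body_points().mean(axis=0))
        assert d <= 2.0
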