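import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trip3p import (DegenerateGeometryError, RetinalImage, TriangleShape,
                    ValidationError, project_vertices, rays_from_image,
                    shape_from_orientation, side_lengths)

from conftest import frontoparallel_equilateral, random_placed_triangle


class TestTriangleShape:
    def test_omega_c_derived(self):
        s = TriangleShape(30.0, 60.0)
        assert s.omega_C == pytest.approx(90.0, abs=1e-9)
        assert sum(s.angles) == pytest.approx(180.0, abs=1e-9)

    @pytest.mark.parametrize("wA,wB", [
        (0.0, 90.0), (-5.0, 90.0), (180.0, 10.0),
        (90.0, 90.0),      # omega_C = 0
        (100.0, 100.0),    # omega_C < 0
        (np.nan, 60.0),
    ])
    def test_invalid_shapes_rejected(self, wA, wB):
        with pytest.raises(ValidationError):
            TriangleShape(wA, wB)

    def test_study_bounds_flag(self):
        assert TriangleShape(60.0, 60.0).within_study_bounds()
        assert not TriangleShape(5.0, 90.0).within_study_bounds()
        assert not TriangleShape(85.0, 86.0).within_study_bounds()  # omega_C = 9

    @given(wA=st.floats(1.0, 178.0), wB=st.floats(1.0, 178.0))
    @settings(max_examples=200, deadline=None)
    def test_law_of_sines_identity(self, wA, wB):
        if not 0.5 < 180.0 - wA - wB < 179.5:
            return
        s = TriangleShape(wA, wB)
        a, b, c = side_lengths(s)
        sines = np.sin(np.deg2rad(s.angles))
        ratios = np.array([a, b, c]) / sines
        assert np.allclose(ratios, ratios[0], rtol=1e-9)


class TestRetinalImage:
    @pytest.mark.parametrize("thetas", [
        (0.0, 10.0, 10.0), (10.0, 10.0, 180.0), (-1.0, 10.0, 10.0),
        (150.0, 150.0, 100.0),   # sum >= 360
        (5.0, 10.0, 20.0),       # triangle inequality
        (20.0, 5.0, 10.0),
        (10.0, 20.0, 5.0),
    ])
    def test_invalid_images_rejected(self, thetas):
        with pytest.raises(ValidationError):
            RetinalImage(*thetas)

    def test_boundary_equality_rejected(self):
        with pytest.raises(ValidationError):
            RetinalImage(10.0, 10.0, 20.0)

    def test_valid_image(self):
        img = RetinalImage(9.0, 10.0, 11.0)
        assert img.thetas == (9.0, 10.0, 11.0)
        assert img.max_angle == 11.0


class TestSideLengths:
    def test_equilateral(self):
        assert side_lengths(TriangleShape(60.0, 60.0)) == pytest.approx(
            (1.0, 1.0, 1.0))

    def test_right_isosceles(self):
        got = side_lengths(TriangleShape(90.0, 45.0))
        assert got == pytest.approx((np.sqrt(2.0), 1.0, 1.0))

    def test_30_60_90(self):
        got = side_lengths(TriangleShape(30.0, 60.0))
        assert got == pytest.approx((0.5, np.sqrt(3.0) / 2.0, 1.0))


class TestRaysFromImage:
    @pytest.mark.parametrize("theta", [10.0, 60.0, 90.0])
    def test_pairwise_angles_reproduced(self, theta):
        img = RetinalImage(theta, theta, theta)
        rays = rays_from_image(img)
        assert rays.pairwise_angles() == pytest.approx(img.thetas, abs=1e-9)

    def test_unit_norm_and_convention(self):
        rays = rays_from_image(RetinalImage(9.0, 10.0, 11.0))
        for v in (rays.V_A, rays.V_B, rays.V_C):
            assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(rays.V_A, [0.0, 0.0, 1.0])
        assert rays.V_B[0] > 0 and rays.V_B[1] == 0.0
        assert rays.V_C[1] > 0

    def test_orthogonal_rays(self):
        rays = rays_from_image(RetinalImage(90.0, 90.0, 90.0))
        assert np.allclose(rays.V_B, [1.0, 0.0, 0.0], atol=1e-12)
        assert np.allclose(rays.V_C, [0.0, 1.0, 0.0], atol=1e-12)


class TestProjectVertices:
    def test_closed_form_example(self):
        img = project_vertices([0, 0, 10], [1, 0, 10], [0, 1, 10])
        expected_ab = np.degrees(np.arctan(1.0 / 10.0))
        cos_bc = 100.0 / 101.0
        expected_bc = np.degrees(np.arccos(cos_bc))
        assert img.theta_AB == pytest.approx(expected_ab, abs=1e-9)
        assert img.theta_CA == pytest.approx(expected_ab, abs=1e-9)
        assert img.theta_BC == pytest.approx(expected_bc, abs=1e-9)

    def test_scale_invariance(self):
        pts = np.array([[0, 0, 10], [1, 0, 10], [0, 1, 10]], dtype=float)
        img1 = project_vertices(*pts)
        img7 = project_vertices(*(7.0 * pts))
        assert img7.thetas == pytest.approx(img1.thetas, abs=1e-12)

    def test_vertex_at_origin_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            project_vertices([0, 0, 0], [1, 0, 10], [0, 1, 10])

    def test_collinear_with_origin_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            project_vertices([0, 0, 5], [0, 0, 10], [0, 1, 10])


class TestShapeFromOrientation:
    def test_equilateral_by_symmetry(self):
        img = RetinalImage(10.0, 10.0, 10.0)
        rays = rays_from_image(img)
        axis = rays.V_A + rays.V_B + rays.V_C
        axis /= np.linalg.norm(axis)
        shape, size = shape_from_orientation(img, axis, 10.0)
        assert shape.angles == pytest.approx((60.0, 60.0, 60.0), abs=1e-8)
        assert size > 0

    def test_round_trip_recovers_shape(self, rng):
        for _ in range(25):
            shape, image, _, pts = random_placed_triangle(rng)
            normal = np.cross(pts[1] - pts[0], pts[2] - pts[0])
            normal /= np.linalg.norm(normal)
            dist = float(normal @ pts[0])
            if dist < 0:
                normal, dist = -normal, -dist
            if dist < 1e-6:
                continue
            # the canonical ray frame differs from the placement frame by a
            # rotation, so recover the plane in the canonical frame instead
            got, size = _recover_in_canonical_frame(image, pts)
            assert got.angles == pytest.approx(shape.angles, abs=1e-8)
            assert size == pytest.approx(1.0, rel=1e-8)

    def test_distance_scales_size_only(self):
        img = RetinalImage(9.0, 10.0, 11.0)
        n = np.array([0.0, 0.0, 1.0])
        s1, size1 = shape_from_orientation(img, n, 10.0)
        s2, size2 = shape_from_orientation(img, n, 20.0)
        assert s2.angles == pytest.approx(s1.angles, abs=1e-10)
        assert size2 == pytest.approx(2.0 * size1, rel=1e-12)

    def test_plane_parallel_to_ray_rejected(self):
        img = RetinalImage(90.0, 90.0, 90.0)
        # normal perpendicular to V_A = +z
        with pytest.raises(DegenerateGeometryError):
            shape_from_orientation(img, [1.0, 0.0, 0.0], 5.0)

    def test_plane_behind_eye_rejected(self):
        img = RetinalImage(9.0, 10.0, 11.0)
        with pytest.raises(DegenerateGeometryError):
            shape_from_orientation(img, [0.0, 0.0, -1.0], 5.0)

    def test_frontoparallel_equilateral_round_trip(self):
        # the frontoparallel plane of the original placement maps to the
        # plane normal to the rays' symmetry axis in the canonical frame;
        # its offset (10) is rotation-invariant
        shape, image, pts = frontoparallel_equilateral(10.0)
        rays = rays_from_image(image)
        axis = rays.V_A + rays.V_B + rays.V_C
        axis /= np.linalg.norm(axis)
        got, size = shape_from_orientation(image, axis, 10.0)
        assert got.angles == pytest.approx(shape.angles, abs=1e-8)
        assert size == pytest.approx(1.0, rel=1e-9)


def _recover_in_canonical_frame(image, pts):
    """Re-express the true triangle plane in the canonical ray frame."""
    from trip3p import rays_from_image

    units = pts / np.linalg.norm(pts, axis=1, keepdims=True)
    rays = rays_from_image(image)
    # rotation mapping the placement-frame rays onto the canonical rays
    target = np.stack([rays.V_A, rays.V_B, rays.V_C])
    rot, _, _, _ = np.linalg.lstsq(units, target, rcond=None)
    canon_pts = pts @ rot
    normal = np.cross(canon_pts[1] - canon_pts[0], canon_pts[2] - canon_pts[0])
    normal /= np.linalg.norm(normal)
    dist = float(normal @ canon_pts[0])
    if dist < 0:
        normal, dist = -normal, -dist
    return shape_from_orientation(image, normal, dist)
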