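"""Rotation algebra, plane-induced homographies and their independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.transform import ProjectiveTransform

from emtmosaic.errors import DegenerateGeometryError, InfinitePointError
from emtmosaic.geometry import (
    Homography,
    Intrinsics,
    Plane,
    Pose,
    apply_homography,
    canonicalize,
    chain_compose,
    exp_so3,
    log_so3,
    pairwise_homography,
    pixel_to_normalized,
    plane_homography,
    plane_to_spherical,
    pose_compose,
    pose_inverse,
    normalized_to_pixel,
    spherical_to_plane,
)
from conftest import random_pose


def rodrigues(r):
    """Independent closed-form rotation oracle."""
    r = np.asarray(r, float)
    th = np.linalg.norm(r)
    S = np.array([[0, -r[2], r[1]], [r[2], 0, -r[0]], [-r[1], r[0], 0]])
    if th < 1e-12:
        return np.eye(3) + S
    return np.eye(3) + np.sin(th) / th * S + (1 - np.cos(th)) / th**2 * (S @ S)


def project_on_plane_points(pose, plane, K, q_mosaic):
    """Ray-plane oracle: back-project mosaic pixels onto the plane, then image
    them with the pinhole model of the camera at ``pose`` (extrinsics [R|-t])."""
    rays = np.column_stack([q_mosaic, np.ones(len(q_mosaic))]) @ K.inverse.T
    lam = 1.0 / (rays @ plane.pi)
    X = rays * lam[:, None]
    Xc = X @ exp_so3(pose.r).T - pose.t
    proj = Xc @ K.matrix.T
    return proj[:, :2] / proj[:, 2:3]


class TestRotations:
    def test_exp_zero_is_identity(self):
        assert np.allclose(exp_so3([0, 0, 0]), np.eye(3))

    def test_exp_quarter_turn_about_z(self):
        R = exp_so3([0, 0, np.pi / 2])
        assert np.allclose(R @ [1, 0, 0], [0, 1, 0], atol=1e-12)

    def test_exp_matches_rodrigues_oracle(self, rng):
        for _ in range(100):
            r = rng.normal(0, 1, 3)
            n = np.linalg.norm(r)
            if n >= np.pi:
                r *= (np.pi - 1e-6) / n
            assert np.allclose(exp_so3(r), rodrigues(r), atol=1e-12)

    def test_log_identity_and_roundtrip(self):
        assert np.allclose(log_so3(np.eye(3)), 0)
        r = np.array([0.1, -0.2, 0.3])
        assert np.allclose(log_so3(exp_so3(r)), r, atol=1e-12)

    def test_log_near_pi_roundtrip(self, rng):
        for _ in range(20):
            axis = rng.normal(0, 1, 3)
            axis /= np.linalg.norm(axis)
            r = axis * (np.pi - 1e-6)
            assert np.linalg.norm(log_so3(exp_so3(r)) - r) < 1e-6

    def test_log_rejects_non_rotation(self):
        with pytest.raises(ValueError):
            log_so3(np.eye(3) * 2.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-2.0, 2.0), min_size=3, max_size=3))
    def test_exp_log_roundtrip_property(self, r):
        r = np.asarray(r)
        n = np.linalg.norm(r)
        if n >= np.pi - 1e-6:
            r *= (np.pi - 1e-3) / n
        assert np.linalg.norm(log_so3(exp_so3(r)) - r) < 1e-8


class TestPoses:
    def test_compose_identity_and_inverse(self, rng):
        x = random_pose(rng)
        ident = Pose.identity()
        assert np.allclose(pose_compose(x, ident).as_vector(), x.as_vector())
        round_ = pose_compose(x, pose_inverse(x))
        assert np.allclose(round_.as_vector(), 0, atol=1e-12)

    def test_compose_associative_vs_matrix_oracle(self, rng):
        for _ in range(20):
            a, b, c = (random_pose(rng) for _ in range(3))
            left = pose_compose(a, pose_compose(b, c)).matrix()
            right = pose_compose(pose_compose(a, b), c).matrix()
            oracle = a.matrix() @ b.matrix() @ c.matrix()
            assert np.allclose(left, right, atol=1e-10)
            assert np.allclose(left, oracle, atol=1e-10)

    def test_pose_requires_small_rotation(self):
        with pytest.raises(ValueError):
            Pose([np.pi, 0, 0], [0, 0, 0])


class TestPlaneHomography:
    def test_identity_pose_gives_identity(self, intrinsics, plane50):
        H = plane_homography(Pose.identity(), plane50, intrinsics)
        assert np.allclose(H.H / H.H[2, 2], np.eye(3), atol=1e-12)

    def test_optical_axis_translation_scales_about_principal_point(self, intrinsics):
        d, tau = 50.0, 10.0
        plane = Plane.from_normal_distance([0, 0, 1], d)
        H = plane_homography(Pose([0, 0, 0], [0, 0, tau]), plane, intrinsics)
        c = np.array([intrinsics.cx, intrinsics.cy])
        assert np.allclose(apply_homography(H, c), c, atol=1e-9)
        out = apply_homography(H, c + [10.0, 0.0])
        scale = d / (d - tau)
        assert np.allclose(out, c + [10.0 * scale, 0.0], atol=1e-9)

    def test_matches_dlt_fit_on_projected_points(self, intrinsics, plane50, rng):
        pose = random_pose(rng, rot_scale=0.1, trans_scale=5.0)
        q = rng.uniform(40, 330, (12, 2))
        q_img = project_on_plane_points(pose, plane50, intrinsics, q)
        tf = ProjectiveTransform.from_estimate(q, q_img)
        assert tf
        H = plane_homography(pose, plane50, intrinsics)
        a, b = canonicalize(H.H), canonicalize(tf.params)
        assert np.allclose(a, b, atol=1e-8)

    def test_ray_plane_oracle_50_points(self, intrinsics, rng):
        plane = Plane.from_normal_distance([0.05, -0.02, 1.0], 50.0)
        for _ in range(5):
            pose = random_pose(rng, rot_scale=0.05, trans_scale=5.0)
            H = plane_homography(pose, plane, intrinsics)
            q = rng.uniform(0, 350, (50, 2))
            assert np.abs(
                apply_homography(H, q)
                - project_on_plane_points(pose, plane, intrinsics, q)
            ).max() < 1e-8

    def test_camera_on_plane_is_degenerate(self, intrinsics):
        # camera center c = R^T t on the plane pi . c = 1 -> singular map
        plane = Plane.from_normal_distance([0, 0, 1], 50.0)
        with pytest.raises(DegenerateGeometryError):
            plane_homography(Pose([0, 0, 0], [0, 0, 50.0]), plane, intrinsics)


class TestPairwiseAndChains:
    def test_identical_poses_give_identity(self, intrinsics, plane50, rng):
        x = random_pose(rng, 0.05, 5.0)
        H = pairwise_homography(x, x, plane50, intrinsics)
        assert np.allclose(H.H / H.H[2, 2], np.eye(3), atol=1e-9)

    def test_pairwise_matches_dlt_on_synthesized_projections(self, intrinsics, plane50, rng):
        xa = random_pose(rng, 0.05, 4.0)
        xb = random_pose(rng, 0.05, 4.0)
        q = rng.uniform(50, 320, (20, 2))
        img_a = project_on_plane_points(xa, plane50, intrinsics, q)
        img_b = project_on_plane_points(xb, plane50, intrinsics, q)
        tf = ProjectiveTransform.from_estimate(img_a, img_b)
        assert tf
        H = pairwise_homography(xb, xa, plane50, intrinsics)
        assert np.allclose(canonicalize(H.H), canonicalize(tf.params), atol=1e-7)

    def test_group_consistency(self, intrinsics, plane50, rng):
        xs = [random_pose(rng, 0.05, 4.0) for _ in range(3)]
        h21 = pairwise_homography(xs[2], xs[1], plane50, intrinsics)
        h10 = pairwise_homography(xs[1], xs[0], plane50, intrinsics)
        chained = canonicalize(h21.H @ h10.H)
        H2 = plane_homography(xs[2], plane50, intrinsics)
        H0 = plane_homography(xs[0], plane50, intrinsics)
        direct = canonicalize(H2.H @ np.linalg.inv(H0.H))
        cos_dist = 1 - np.abs(np.sum(chained * direct))
        assert cos_dist < 1e-10

    def test_chain_compose_identities_and_translations(self):
        ident = [Homography.identity()] * 5
        assert np.allclose(chain_compose(ident).H, canonicalize(np.eye(3)))
        t1 = Homography([[1, 0, 3], [0, 1, 4], [0, 0, 1]])
        t2 = Homography([[1, 0, 1], [0, 1, 1], [0, 0, 1]])
        out = chain_compose([t1, t2])
        expect = canonicalize(np.array([[1, 0, 4], [0, 1, 5], [0, 0, 1.0]]))
        assert np.allclose(out.H, expect, atol=1e-12)

    def test_chain_compose_empty_raises(self):
        with pytest.raises(ValueError):
            chain_compose([])

    def test_chain_over_poses_equals_direct_ratio(self, intrinsics, plane50, rng):
        xs = [random_pose(rng, 0.03, 3.0) for _ in range(5)]
        pairs = [pairwise_homography(xs[k + 1], xs[k], plane50, intrinsics)
                 for k in range(4)]
        chained = chain_compose(pairs).H
        H4 = plane_homography(xs[4], plane50, intrinsics)
        H0 = plane_homography(xs[0], plane50, intrinsics)
        assert np.allclose(chained, canonicalize(H4.H @ np.linalg.inv(H0.H)), atol=1e-9)


class TestApplyHomography:
    def test_identity_and_translation(self):
        assert np.allclose(apply_homography(Homography.identity(), [10, 20]), [10, 20])
        T = Homography([[1, 0, 3], [0, 1, 4], [0, 0, 1]])
        assert np.allclose(apply_homography(T, [0, 0]), [3, 4])

    def test_matches_scalar_arithmetic(self, rng):
        for _ in range(20):
            M = rng.normal(0, 1, (3, 3)) + 3 * np.eye(3)
            q = rng.uniform(-5, 5, 2)
            den = M[2, 0] * q[0] + M[2, 1] * q[1] + M[2, 2]
            expect = [
                (M[0, 0] * q[0] + M[0, 1] * q[1] + M[0, 2]) / den,
                (M[1, 0] * q[0] + M[1, 1] * q[1] + M[1, 2]) / den,
            ]
            assert np.allclose(apply_homography(M, q), expect, atol=1e-10)

    def test_point_at_infinity_raises(self):
        M = np.array([[1.0, 0, 0], [0, 1, 0], [0, -1, 1]])
        with pytest.raises(InfinitePointError):
            apply_homography(M, [0.0, 1.0])


class TestCanonicalization:
    def test_idempotent_bit_exact(self, rng):
        for _ in range(20):
            M = rng.normal(0, 1, (3, 3))
            once = canonicalize(M)
            twice = canonicalize(once)
            assert (once == twice).all()

    def test_sign_fixed_by_bottom_right(self):
        M = -5.0 * np.eye(3)
        out = canonicalize(M)
        assert out[2, 2] > 0
        assert np.isclose(np.linalg.norm(out), 1.0)


class TestSphericalConversion:
    def test_axis_aligned(self):
        az, el, d = plane_to_spherical(Plane([0, 0, 1 / 50]))
        assert el == pytest.approx(90.0)
        assert d == pytest.approx(50.0)

    def test_roundtrip_random(self, rng):
        for _ in range(100):
            n = rng.normal(0, 1, 3)
            n[2] = abs(n[2]) + 0.1
            p = Plane.from_normal_distance(n, rng.uniform(10, 200))
            az, el, d = plane_to_spherical(p)
            back = spherical_to_plane(az, el, d)
            assert np.allclose(back.pi, p.pi, atol=1e-10)

    def test_scaling_pi_halves_distance_keeps_angles(self):
        p = Plane([0.003, -0.001, 0.02])
        az1, el1, d1 = plane_to_spherical(p)
        az2, el2, d2 = plane_to_spherical(Plane(2 * p.pi))
        assert d2 == pytest.approx(d1 / 2)
        assert az2 == pytest.approx(az1)
        assert el2 == pytest.approx(el1)


def test_pixel_normalized_roundtrip(intrinsics, rng):
    q = rng.uniform(0, 360, (30, 2))
    back = normalized_to_pixel(intrinsics, pixel_to_normalized(intrinsics, q))
    assert np.allclose(back, q, atol=1e-12)
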