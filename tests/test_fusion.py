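"""Residual blocks, the pairwise DLT estimator, and the joint solver."""

import numpy as np
import pytest

from emtmosaic.correspondences import CorrespondenceCollection, CorrespondenceSet
from emtmosaic.errors import BrokenChainError, InsufficientDataError
from emtmosaic.estimators import BundleAdjustmentMosaicker
from emtmosaic.evaluate import emt_only_composition, evaluate_homographies
from emtmosaic.fusion import (
    EMTNoiseModel,
    MotionModel,
    ProblemState,
    SolveOptions,
    VisualNoiseModel,
    emt_residuals,
    estimate_pairwise_homography,
    motion_prior_residuals,
    pairvis_chain,
    predict_pose,
    solve_bundle,
    visual_residuals,
)
from emtmosaic.geometry import Homography, Plane, Pose, apply_homography, canonicalize, exp_so3
from conftest import random_pose


class TestPredictPose:
    def test_zero_velocity(self, rng):
        x = random_pose(rng)
        mu = predict_pose(x, x)
        assert np.allclose(mu.as_vector(), x.as_vector(), atol=1e-12)

    def test_pure_translation_extrapolates_linearly(self):
        a = Pose([0, 0, 0], [1.0, 0, 0])
        b = Pose([0, 0, 0], [0, 0, 0])
        assert np.allclose(predict_pose(a, b).t, [2.0, 0, 0])

    def test_matches_matrix_oracle(self, rng):
        for _ in range(10):
            a, b = random_pose(rng, 0.2, 5.0), random_pose(rng, 0.2, 5.0)
            Tbar = a.matrix() @ np.linalg.inv(b.matrix()) @ a.matrix()
            mu = predict_pose(a, b)
            assert np.allclose(mu.matrix(), Tbar, atol=1e-10)


class TestVisualResiduals:
    def test_single_correspondence_scalar_oracle(self, intrinsics, plane50, rng):
        xa, xb = random_pose(rng, 0.05, 4.0), random_pose(rng, 0.05, 4.0)
        qa = np.array([120.0, 150.0])
        qb = np.array([130.0, 140.0])
        coll = CorrespondenceCollection(
            [CorrespondenceSet((0, 1), qa[None], qb[None])])
        state = ProblemState([xa, xb], plane50)
        sigma_v = 2.0
        res = visual_residuals(state, coll, VisualNoiseModel(sigma_v, "none"),
                               intrinsics)
        # independent scalar evaluation of (p_B - H_l H_m^{-1} p_A) / sigma
        K = intrinsics.matrix
        Ki = intrinsics.inverse

        def Hmat(x):
            return K @ (exp_so3(x.r) - np.outer(x.t, plane50.pi)) @ Ki

        H = Hmat(xb) @ np.linalg.inv(Hmat(xa))
        hom = H @ np.array([qa[0], qa[1], 1.0])
        mu = hom[:2] / hom[2]
        assert np.allclose(res, (qb - mu) / sigma_v, atol=1e-10)

    def test_per_pair_count_invariant_to_duplication(self, intrinsics, plane50, rng):
        xa, xb = random_pose(rng, 0.05, 4.0), random_pose(rng, 0.05, 4.0)
        pa = rng.uniform(50, 300, (6, 2))
        pb = rng.uniform(50, 300, (6, 2))
        model = VisualNoiseModel(1.0, "per-pair-count")
        base = visual_residuals(
            ProblemState([xa, xb], plane50),
            CorrespondenceCollection([CorrespondenceSet((0, 1), pa, pb)]),
            model, intrinsics)
        doubled = visual_residuals(
            ProblemState([xa, xb], plane50),
            CorrespondenceCollection([CorrespondenceSet(
                (0, 1), np.vstack([pa, pa]), np.vstack([pb, pb]))]),
            model, intrinsics)
        assert np.isclose(base @ base, doubled @ doubled, rtol=1e-12)


class TestEmtResiduals:
    def test_exact_measurements_give_zero(self, rng):
        poses = [random_pose(rng) for _ in range(4)]
        state = ProblemState(poses, Plane([0, 0, 0.02]))
        res = emt_residuals(state, poses, EMTNoiseModel(np.ones(6)))
        assert np.allclose(res, 0.0)

    def test_three_four_offset_gives_norm_25(self):
        x = Pose.identity()
        z = Pose([0, 0, 0], [3.0, 4.0, 0.0])
        state = ProblemState([x], Plane([0, 0, 0.02]))
        res = emt_residuals(state, [z], EMTNoiseModel(np.ones(6)))
        assert np.isclose(res @ res, 25.0)

    def test_matches_quadratic_form_oracle(self, rng):
        poses = [random_pose(rng) for _ in range(5)]
        zs = [random_pose(rng) for _ in range(5)]
        var = rng.uniform(0.1, 2.0, 6)
        res = emt_residuals(ProblemState(poses, Plane([0, 0, 0.02])), zs,
                            EMTNoiseModel(var))
        oracle = sum(
            (z.as_vector() - x.as_vector()) @ np.diag(1 / var)
            @ (z.as_vector() - x.as_vector())
            for z, x in zip(zs, poses)
        )
        assert np.isclose(res @ res, oracle, rtol=1e-12)


class TestMotionPriorResiduals:
    def test_two_frame_problem_is_empty(self, rng):
        state = ProblemState([random_pose(rng), random_pose(rng)], Plane([0, 0, 0.02]))
        assert motion_prior_residuals(state, MotionModel()).size == 0

    def test_matches_independent_evaluation(self, rng):
        poses = [random_pose(rng, 0.2, 5.0) for _ in range(3)]
        var = rng.uniform(0.1, 2.0, 6)
        res = motion_prior_residuals(
            ProblemState(poses, Plane([0, 0, 0.02])), MotionModel(var))
        mu = predict_pose(poses[1], poses[0])
        diff = poses[2].as_vector() - mu.as_vector()
        oracle = diff @ np.diag(1 / var) @ diff
        assert np.isclose(res @ res, oracle, rtol=1e-10)


class TestPairwiseHomographyEstimation:
    def test_exact_minimal_case(self, rng):
        H = np.array([[1.1, 0.02, 5.0], [-0.01, 0.95, -3.0], [1e-4, -2e-4, 1.0]])
        pa = np.array([[0.0, 0], [100, 0], [0, 100], [100, 100]])
        pb = apply_homography(H, pa)
        est = estimate_pairwise_homography(CorrespondenceSet((0, 1), pa, pb))
        assert np.allclose(est.H, canonicalize(H), atol=1e-8)

    def test_noise_free_synthetic_transfer_error(self, noisefree_seq):
        s = noisefree_seq.correspondences.get(0, 1)
        est = estimate_pairwise_homography(s)
        pred = apply_homography(est, s.points_a)
        assert np.linalg.norm(pred - s.points_b, axis=1).mean() < 1e-8

    def test_three_points_insufficient(self):
        s = CorrespondenceSet((0, 1), np.random.rand(3, 2), np.random.rand(3, 2))
        with pytest.raises(InsufficientDataError):
            estimate_pairwise_homography(s)

    def test_collinear_points_rejected(self):
        pa = np.column_stack([np.arange(6.0), np.arange(6.0)])
        s = CorrespondenceSet((0, 1), pa, pa + 1.0)
        with pytest.raises(InsufficientDataError):
            estimate_pairwise_homography(s)


class TestPairvisChain:
    def test_noise_free_recovery(self, noisefree_seq):
        Hs = pairvis_chain(noisefree_seq.correspondences, noisefree_seq.n_frames)
        rep = evaluate_homographies(Hs, noisefree_seq.ground_truth.gt_homographies,
                                    noisefree_seq.frame_size, 20)
        assert rep.e_M < 1e-6

    def test_chain_length_is_n_minus_one(self, noisefree_seq):
        n = noisefree_seq.n_frames
        assert len(noisefree_seq.correspondences.subset(
            [(k, k + 1) for k in range(n - 1)])) == n - 1
        assert len(pairvis_chain(noisefree_seq.correspondences, n)) == n

    def test_missing_pair_breaks_chain(self, noisefree_seq):
        broken = noisefree_seq.correspondences.without_frames({5})
        with pytest.raises(BrokenChainError) as exc:
            pairvis_chain(broken, noisefree_seq.n_frames)
        assert exc.value.gap == (4, 5)


class TestSolveBundle:
    def test_noise_free_exact_recovery_from_perturbed_plane(self, noisefree_seq):
        gt = noisefree_seq.ground_truth
        est = BundleAdjustmentMosaicker(
            sigma_emt_rot_deg=1e-4, sigma_emt_trans_mm=1e-4).fit(noisefree_seq)
        t_err = max(np.linalg.norm(p.t - q.t) for p, q in zip(est.poses_, gt.poses))
        assert t_err < 1e-6
        assert (np.linalg.norm(est.plane_.pi - gt.plane.pi)
                / np.linalg.norm(gt.plane.pi)) < 1e-8

    def test_plane_only_subproblem_recovers_plane(self, noisefree_seq):
        gt = noisefree_seq.ground_truth
        state = ProblemState([p.copy() for p in gt.poses],
                             Plane.from_normal_distance([0, 0, 1], 80.0),
                             np.zeros(noisefree_seq.n_frames, bool), True)
        new, report = solve_bundle(
            state, noisefree_seq.correspondences, Z=None,
            visual_model=VisualNoiseModel(1.0, "none"),
            options=SolveOptions(intrinsics=noisefree_seq.intrinsics,
                                 use_motion_prior=False),
        )
        assert report.final_cost <= report.initial_cost
        assert (np.linalg.norm(new.plane.pi - gt.plane.pi)
                / np.linalg.norm(gt.plane.pi)) < 1e-8

    def test_descent_from_emt_initialization(self, noisy_seq20):
        est = BundleAdjustmentMosaicker().fit(noisy_seq20)
        assert est.report_.final_cost <= est.report_.initial_cost

    def test_objective_equals_sum_of_term_costs(self, noisy_seq20):
        # -2 log posterior (up to a constant) = C_v + C_EMT + C_p, each
        # recomputed from its residual block by independent summation
        rng = np.random.default_rng(8)
        poses = [Pose(p.r + rng.normal(0, 0.01, 3), p.t + rng.normal(0, 0.5, 3))
                 for p in noisy_seq20.ground_truth.poses]
        state = ProblemState(poses, Plane([1e-4, -2e-4, 1 / 48.0]))
        vm, em, mm = VisualNoiseModel(), EMTNoiseModel(), MotionModel()
        rv = visual_residuals(state, noisy_seq20.correspondences, vm,
                              noisy_seq20.intrinsics)
        re = emt_residuals(state, noisy_seq20.emt, em)
        rp = motion_prior_residuals(state, mm)
        total_from_blocks = rv @ rv + re @ re + rp @ rp
        stacked = np.concatenate([rv, re, rp])
        assert np.isclose(stacked @ stacked, total_from_blocks, rtol=1e-12)

    def test_nonfinite_initialization_rejected(self, noisy_seq20):
        poses = [p.copy() for p in noisy_seq20.emt]
        state = ProblemState(poses, Plane([0, 0, 0.02]))
        bad = CorrespondenceCollection([CorrespondenceSet(
            (0, 1), np.array([[np.nan, 1.0]]), np.array([[2.0, 3.0]]))])
        with pytest.raises(ValueError, match="non-finite"):
            solve_bundle(state, bad, Z=noisy_seq20.emt,
                         options=SolveOptions(intrinsics=noisy_seq20.intrinsics))


class TestFusionQuality:
    def test_fusion_beats_either_source_alone(self, noisy_seq30):
        gt = noisy_seq30.ground_truth
        ba = BundleAdjustmentMosaicker().fit(noisy_seq30)
        e_fusion = evaluate_homographies(
            ba.homographies_, gt.gt_homographies, noisy_seq30.frame_size, 50).e_M
        emt_h = emt_only_composition(noisy_seq30.emt, gt.plane, noisy_seq30.intrinsics)
        e_emt = evaluate_homographies(
            emt_h, gt.gt_homographies, noisy_seq30.frame_size, 50).e_M
        assert e_fusion <= e_emt
        rmse = np.sqrt(np.mean([
            np.sum((p.t - q.t) ** 2) / 3.0 for p, q in zip(ba.poses_, gt.poses)]))
        assert rmse <= 1.0  # the EMT translation noise std at nu = 1

    def test_vis_only_gauge_invariance_of_visual_cost(self, noisy_seq20):
        costs = []
        for d0 in (80.0, 120.0):
            est = BundleAdjustmentMosaicker(
                use_emt=False, use_motion_prior=False,
                plane_init=Plane.from_normal_distance([0, 0, 1], d0),
            ).fit(noisy_seq20)
            costs.append(est.report_.cost_terms["C_v"])
        assert np.isclose(costs[0], costs[1], rtol=1e-3)
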