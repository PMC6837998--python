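"""Robust alignment, correspondences and annealed coefficient fitting."""

import numpy as np
import pytest

from osteomorph import (
    bidirectional_correspondences,
    build_model,
    fit_unseen,
    project,
    reconstruct,
    robust_align,
    solve_coefficients,
)
from osteomorph.fitting import RobustnessError, default_schedule
from osteomorph.geometry import _umeyama, flatten
from osteomorph.synthetic import make_template

from conftest import random_rotation


@pytest.fixture
def bone_points():
    return make_template(100, "bone_like").points


@pytest.fixture
def posed_copy(bone_points, rng):
    Q = random_rotation(rng)
    return bone_points @ Q.T + np.array([5.0, 2.0, -1.0])


class TestBidirectionalCorrespondences:
    def test_identical_sets_give_identity_matches(self, bone_points):
        corr = bidirectional_correspondences(bone_points, bone_points)
        np.testing.assert_array_equal(corr.index_a, corr.index_b)
        np.testing.assert_allclose(corr.distance, 0.0)
        assert len(corr) == 2 * len(bone_points)

    def test_matches_brute_force_both_directions(self, rng):
        a = rng.normal(size=(3, 3)) * 10
        b = rng.normal(size=(3, 3)) * 10
        corr = bidirectional_correspondences(a, b)
        D = np.array([[np.linalg.norm(p - q) for q in b] for p in a])
        for i in range(3):  # a -> b block
            assert corr.index_b[i] == D[i].argmin()
        for j in range(3):  # b -> a block
            assert corr.index_a[3 + j] == D[:, j].argmin()

    def test_displaced_point_only_matched_in_reverse_direction(self, rng):
        a = rng.normal(size=(5, 3))
        b = a.copy()
        b[2] += 1000.0
        corr = bidirectional_correspondences(a, b)
        ab = corr.direction == "ab"
        assert 2 not in corr.index_b[ab]           # nobody maps onto it
        ba = corr.direction == "ba"
        assert 2 in corr.index_b[ba]               # but it still maps back


class TestRobustAlign:
    def test_clean_copy_keeps_all_inliers(self, bone_points, posed_copy):
        transform, mask = robust_align(posed_copy, bone_points, alpha=0.05)
        assert mask.all()
        rmsd = np.sqrt(((transform.apply(posed_copy) - bone_points) ** 2).sum()
                       / len(bone_points))
        assert rmsd <= 1e-8

    def test_pinocchio_bump_excluded(self, bone_points, posed_copy):
        # 6 mm bump on 2% of contiguous landmarks: robust alignment keeps the
        # clean region exact while plain least squares drags everything
        bumped = posed_copy.copy()
        bump_idx = np.array([40, 41])
        bumped[bump_idx] += 6.0 / np.sqrt(3)
        clean = np.ones(len(bone_points), dtype=bool)
        clean[bump_idx] = False

        transform, mask = robust_align(bumped, bone_points, alpha=0.05)
        resid = np.linalg.norm(transform.apply(bumped) - bone_points, axis=1)
        robust_rmsd = np.sqrt((resid[clean] ** 2).mean())

        R, t, _ = _umeyama(bumped, bone_points, False)
        plain = np.linalg.norm(bumped @ R.T + t - bone_points, axis=1)
        plain_rmsd = np.sqrt((plain[clean] ** 2).mean())

        assert robust_rmsd <= 0.1
        assert plain_rmsd > robust_rmsd
        assert not mask[bump_idx].any()

    def test_aggressive_alpha_stable_on_clean_data(self, bone_points, posed_copy):
        t_ref, _ = robust_align(posed_copy, bone_points, alpha=0.05)
        t_hi, _ = robust_align(posed_copy, bone_points, alpha=0.49)
        delta = t_hi.apply(posed_copy) - t_ref.apply(posed_copy)
        assert np.sqrt((delta**2).sum() / len(bone_points)) <= 1e-3

    def test_cascading_exclusion_raises(self, bone_points, rng):
        # geometrically spread residuals make the trimming cascade until
        # fewer than half of the landmarks survive
        mags = np.geomspace(1e-3, 500.0, len(bone_points))
        dirs = rng.normal(size=bone_points.shape)
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        corrupted = bone_points + mags[:, None] * dirs
        with pytest.raises(RobustnessError):
            robust_align(corrupted, bone_points, alpha=0.05)

    def test_invalid_alpha_rejected(self, bone_points):
        with pytest.raises(ValueError):
            robust_align(bone_points, bone_points, alpha=0.7)


class TestSolveCoefficients:
    @pytest.fixture
    def toy_model(self, rng):
        X = rng.normal(size=(8, 18)) * 4 + 25
        return build_model(X), X

    def test_identity_correspondences_reduce_to_projection(self, toy_model):
        model, X = toy_model
        b = solve_coefficients(model, X[0], model.n_modes)
        np.testing.assert_allclose(b.b, project(model, X[0]).b, atol=1e-8)
        recon = reconstruct(model, b)
        assert np.sqrt(((recon - X[0]) ** 2).sum() / 6) <= 1e-8

    def test_matches_normal_equations_oracle(self, toy_model, rng):
        model, X = toy_model
        target = X[1] + rng.normal(size=18)
        b = solve_coefficients(model, target, 2)
        P = model.eigenvectors[:, :2]
        rhs = target - model.mean_shape
        oracle = np.linalg.solve(P.T @ P, P.T @ rhs)
        np.testing.assert_allclose(b.b, oracle, atol=1e-10)

    def test_duplicated_equations_leave_solution_unchanged(self, toy_model):
        from osteomorph.fitting import Correspondences

        model, X = toy_model
        K = model.n_landmarks
        idx = np.arange(K)
        doubled = Correspondences(
            index_a=np.concatenate([idx, idx]),
            index_b=np.concatenate([idx, idx]),
            distance=np.zeros(2 * K),
            direction=np.array(["ab"] * K + ["ba"] * K),
        )
        b_single = solve_coefficients(model, X[2], 3)
        b_double = solve_coefficients(model, X[2], 3, doubled)
        np.testing.assert_allclose(b_single.b, b_double.b, atol=1e-10)

    def test_too_few_equations_rejected(self, toy_model):
        from osteomorph.fitting import Correspondences

        model, _ = toy_model
        tiny = Correspondences(index_a=np.array([0]), index_b=np.array([0]),
                               distance=np.zeros(1), direction=np.array(["ab"]))
        with pytest.raises(ValueError):
            solve_coefficients(model, np.zeros(18), model.n_modes, tiny)


class TestFitUnseen:
    def test_training_shape_recovered_from_arbitrary_pose(self, small_model, rng):
        model = small_model.model
        row = small_model.training.shapes[7]
        posed = row.reshape(-1, 3) @ random_rotation(rng).T + np.array([30.0, -8.0, 2.0])
        result = fit_unseen(model, posed, schedule=[model.n_modes],
                            identity_correspondences=True)
        # limited only by the model's own span (null-mode cutoff residue)
        from osteomorph import accuracy

        span_limit = accuracy(model, small_model.training, model.n_modes).mean
        assert result.rmse_mm <= max(1e-3, 2 * span_limit)
        b_ref = project(model, row).b
        tol = 1e-3 * np.sqrt(model.eigenvalues[0])
        assert np.abs(result.coeffs.b - b_ref).max() <= tol

    def test_known_coefficients_recovered(self, small_model, rng):
        model = small_model.model
        b_true = np.array([5.0, -2.0, 1.0])
        shape = reconstruct(model, b_true).reshape(-1, 3)
        posed = shape @ random_rotation(rng).T + np.array([-4.0, 11.0, 6.0])
        result = fit_unseen(model, posed, schedule=[1, 2, 3],
                            identity_correspondences=True)
        rel = np.abs(result.coeffs.b - b_true) / np.sqrt(model.eigenvalues[:3])
        assert rel.max() <= 0.01

    def test_single_stage_equals_projection(self, small_model):
        model = small_model.model
        row = small_model.training.shapes[3]
        M = min(model.n_modes, 5)
        result = fit_unseen(model, row.reshape(-1, 3), schedule=[M],
                            identity_correspondences=True)
        np.testing.assert_allclose(result.coeffs.b, project(model, row, M).b,
                                   atol=1e-4)

    def test_rmse_invariant_to_rigid_pretransform(self, small_model, rng):
        model = small_model.model
        b_true = rng.normal(size=4) * np.sqrt(model.eigenvalues[:4])
        shape = reconstruct(model, b_true).reshape(-1, 3)
        res0 = fit_unseen(model, shape, schedule=[4], identity_correspondences=True)
        moved = shape @ random_rotation(rng).T + np.array([50.0, 1.0, -20.0])
        res1 = fit_unseen(model, moved, schedule=[4], identity_correspondences=True)
        assert abs(res0.rmse_mm - res1.rmse_mm) <= 1e-6

    def test_anneal_trace_nonincreasing_on_noiseless_target(self, small_model, rng):
        model = small_model.model
        b_true = rng.normal(size=5) * np.sqrt(model.eigenvalues[:5])
        shape = reconstruct(model, b_true).reshape(-1, 3)
        result = fit_unseen(model, shape, schedule=default_schedule(model),
                            identity_correspondences=True)
        rmses = [r for _, r in result.anneal_trace]
        assert np.all(np.diff(rmses) <= 1e-9)

    def test_outliers_degrade_inlier_fit_marginally(self, small_model, rng):
        # <= 5% outliers of <= 6 mm cost <= 0.1 mm on the inlier-region RMSE
        model = small_model.model
        worst = 0.0
        for seed in range(20):
            gen = np.random.default_rng(seed)
            b_true = gen.normal(size=3) * np.sqrt(model.eigenvalues[:3])
            shape = reconstruct(model, b_true).reshape(-1, 3)
            clean_fit = fit_unseen(model, shape, schedule=[3],
                                   identity_correspondences=True)
            K = shape.shape[0]
            n_out = max(1, int(0.05 * K))
            start = int(gen.integers(K - n_out))
            idx = np.arange(start, start + n_out)
            corrupted = shape.copy()
            corrupted[idx] += gen.normal(size=3) * 0 + 6.0 / np.sqrt(3)
            fit = fit_unseen(model, corrupted, schedule=[3],
                             identity_correspondences=True)
            inlier = np.ones(K, dtype=bool)
            inlier[idx] = False
            recon = reconstruct(model, fit.coeffs).reshape(-1, 3)
            aligned = fit.transform.apply(corrupted)
            rmse_in = np.sqrt((np.linalg.norm(aligned[inlier] - recon[inlier],
                                              axis=1) ** 2).mean())
            worst = max(worst, rmse_in - clean_fit.rmse_mm)
        assert worst <= 0.1

    def test_icp_path_fits_unlabeled_target(self, small_model, rng):
        model = small_model.model
        b_true = np.array([4.0, 1.5, -1.0])
        shape = reconstruct(model, b_true).reshape(-1, 3)
        perm = rng.permutation(shape.shape[0])
        res = fit_unseen(model, shape[perm] + np.array([2.0, -1.0, 0.5]),
                         schedule=[1, 2, 3], identity_correspondences=False)
        assert res.rmse_mm <= 0.2

    def test_schedule_beyond_modes_rejected(self, small_model):
        model = small_model.model
        with pytest.raises(IndexError):
            fit_unseen(model, model.mean_points(), schedule=[model.n_modes + 1])
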