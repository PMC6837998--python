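"""Accuracy, compactness, generalization, specificity and convergence."""

import numpy as np
import pytest

from osteomorph import (
    GeneralizationCurve,
    LandmarkConfiguration,
    PointDistributionModel,
    accuracy,
    build_model,
    compactness,
    detect_convergence,
    generalization_curve,
    generalization_loo,
    modes_for_accuracy,
    modes_for_variance,
    project,
    reconstruct,
    size_dominance,
    specificity,
)
from osteomorph.evaluation import projection_fitter
from osteomorph.geometry import AlignedShapeSet, generalized_procrustes
from osteomorph.model import ShapeModel

from conftest import random_rotation


def _aligned_set(X, scaled=False):
    return AlignedShapeSet(shapes=X, mean_shape=X.mean(axis=0),
                           transforms=None, scaled=scaled, structure="toy")


@pytest.fixture
def toy_training(rng):
    X = rng.normal(size=(5, 12)) * 4 + 30
    return _aligned_set(X)


class TestAccuracy:
    def test_all_modes_reconstruct_perfectly(self, toy_training):
        model = build_model(toy_training)
        assert accuracy(model, toy_training, model.n_modes).mean <= 1e-8

    def test_zero_modes_equal_rmsd_to_mean(self, toy_training):
        model = build_model(toy_training)
        acc = accuracy(model, toy_training, 0)
        per_shape = np.sqrt(
            ((toy_training.shapes - model.mean_shape) ** 2).sum(axis=1) / 4
        )
        assert acc.mean == pytest.approx(per_shape.mean(), abs=1e-12)
        assert acc.sd == pytest.approx(per_shape.std(), abs=1e-12)

    def test_matches_direct_summation_oracle(self, toy_training):
        model = build_model(toy_training)
        acc = accuracy(model, toy_training, 1)
        # hand-rolled loop: project each shape, measure point distances
        errs = []
        for row in toy_training.shapes:
            recon = reconstruct(model, project(model, row, 1).b)
            d = (row - recon).reshape(-1, 3)
            errs.append(np.sqrt((np.linalg.norm(d, axis=1) ** 2).mean()))
        assert acc.mean == pytest.approx(np.mean(errs), abs=1e-10)
        assert acc.sd == pytest.approx(np.std(errs), abs=1e-10)

    def test_out_of_range_modes_rejected(self, toy_training):
        model = build_model(toy_training)
        with pytest.raises(IndexError):
            accuracy(model, toy_training, model.n_modes + 1)


class TestModesForAccuracy:
    def test_infinite_target_reduces_to_variance_rule(self, toy_training):
        model = build_model(toy_training)
        res = modes_for_accuracy(model, toy_training, np.inf, min_variance=0.9)
        assert res.M == modes_for_variance(model, 0.9)
        assert res.reached

    def test_matches_exhaustive_scan(self, rng):
        # 3-mode generator with a noise floor; smallest adequate M by scan
        gen = np.random.default_rng(17)
        U = np.linalg.qr(gen.normal(size=(30, 3)))[0]
        b = gen.normal(size=(40, 3)) * np.sqrt([25.0, 9.0, 1.0])
        X = b @ U.T + gen.normal(scale=0.2, size=(40, 30))
        training = _aligned_set(X)
        model = build_model(training)
        res = modes_for_accuracy(model, training, target_mm=0.25, min_variance=0.5)
        scan = next(
            M for M in range(model.n_modes + 1)
            if accuracy(model, training, M).mean <= 0.25
            and (M > 0 and compactness(model)[M - 1] >= 0.5)
        )
        assert res.M == scan
        assert res.reached

    def test_unreachable_target_flags_full_model(self, toy_training):
        # the 5-shape sample has 4 modes; a sub-numerical target is unreachable
        model = build_model(toy_training)
        res = modes_for_accuracy(model, toy_training, target_mm=1e-15)
        assert res.M == model.n_modes
        assert not res.reached


class TestCompactnessAndSize:
    def test_equal_spectrum(self):
        model = ShapeModel(mean_shape=np.zeros(12), eigenvectors=np.eye(12)[:, :4],
                           eigenvalues=np.ones(4), n_train=5)
        np.testing.assert_allclose(compactness(model), [0.25, 0.5, 0.75, 1.0])
        assert size_dominance(model) == pytest.approx(0.25)

    def test_single_mode(self):
        model = ShapeModel(mean_shape=np.zeros(12), eigenvectors=np.eye(12)[:, :1],
                           eigenvalues=np.array([2.0]), n_train=2)
        np.testing.assert_allclose(compactness(model), [1.0])

    def test_random_spectrum_matches_cumsum_oracle(self, rng):
        lam = np.sort(rng.random(8))[::-1] + 0.1
        model = ShapeModel(mean_shape=np.zeros(30), eigenvectors=np.eye(30)[:, :8],
                           eigenvalues=lam, n_train=9)
        np.testing.assert_allclose(compactness(model), np.cumsum(lam) / lam.sum(),
                                   atol=1e-12)
        assert compactness(model)[-1] == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(compactness(model)) >= 0)


class TestGeneralizationLoo:
    def test_one_mode_population_generalizes_perfectly(self, rng):
        # every shape lies in the span of the mean and a single mode; the mode
        # is orthogonal to the rigid motions so superimposition is exact
        from osteomorph.synthetic import _rigid_motion_basis

        base = rng.normal(size=(8, 3)) * 10
        u = rng.normal(size=24)
        rigid = _rigid_motion_basis(base)
        u -= rigid @ (rigid.T @ u)
        u /= np.linalg.norm(u)
        configs = []
        for i in range(10):
            vec = base.reshape(-1) + (i - 4.5) * 2 * u
            configs.append(LandmarkConfiguration(
                subject_id=str(i), structure="toy", points=vec.reshape(-1, 3)))
        aligned = generalized_procrustes(configs, tol=1e-12)
        gen = generalization_loo(aligned, M_rule=1, gpa_tol=1e-12)
        assert gen.mean <= 1e-6

    def test_matches_explicit_loo_loop(self, rng):
        X = rng.normal(size=(5, 12)) * 3 + 20
        configs = [LandmarkConfiguration(subject_id=str(i), structure="toy",
                                         points=X[i].reshape(-1, 3))
                   for i in range(5)]
        aligned = generalized_procrustes(configs, tol=1e-10)
        got = generalization_loo(aligned, M_rule=2, gpa_tol=1e-10)
        errs = []
        for i in range(5):
            rest = [j for j in range(5) if j != i]
            sub = generalized_procrustes(aligned.subset_configurations(rest),
                                         tol=1e-10)
            fold = build_model(sub)
            errs.append(projection_fitter(fold, aligned.shapes[i].reshape(-1, 3),
                                          min(2, fold.n_modes)).rmse_mm)
        assert got.mean == pytest.approx(np.mean(errs), abs=1e-10)
        assert got.sd == pytest.approx(np.std(errs), abs=1e-10)

    def test_noise_floor_bounds_error(self, study_decomposition):
        # 5-mode population, 0.3 mm noise: the consensus noise floor is
        # 0.3/sqrt(2) ~ 0.21 mm; generalization should sit just above it
        _, consensus = study_decomposition
        idx = np.arange(0, consensus.n_shapes, 2)[:150]
        sub = AlignedShapeSet(
            shapes=consensus.shapes[idx],
            mean_shape=consensus.shapes[idx].mean(axis=0),
            transforms=None, scaled=False,
            configs=[consensus.configs[i] for i in idx],
        )
        gen = generalization_loo(sub, M_rule=0.98)
        floor = 0.3 / np.sqrt(2)
        assert floor * 0.9 <= gen.mean <= floor + 0.15


class TestGeneralizationCurve:
    def test_validates_sizes(self, toy_training):
        with pytest.raises(ValueError):
            generalization_curve(toy_training, sizes=[3, 3], repetitions=2)
        with pytest.raises(ValueError):
            generalization_curve(toy_training, sizes=[2, 10], repetitions=2)

    def test_reproducible_under_seed(self, small_model):
        training = small_model.training
        a = generalization_curve(training, sizes=[5, 10], repetitions=3, rng=5)
        b = generalization_curve(training, sizes=[5, 10], repetitions=3, rng=5)
        np.testing.assert_array_equal(a.mean_rmse_mm, b.mean_rmse_mm)

    def test_curve_decreases_and_approaches_in_sample(self, study_decomposition):
        _, consensus = study_decomposition
        idx = np.arange(0, consensus.n_shapes, 2)[:150]
        sub = AlignedShapeSet(
            shapes=consensus.shapes[idx],
            mean_shape=consensus.shapes[idx].mean(axis=0),
            transforms=None, scaled=False,
            configs=[consensus.configs[i] for i in idx],
        )
        # the latent model has 5 modes; a fixed M rule keeps the comparison
        # between in- and out-of-sample error sharp
        curve = generalization_curve(sub, sizes=[8, 16, 32, 64, 149],
                                     repetitions=10, rng=3, M_rule=5)
        diffs = np.diff(curve.mean_rmse_mm)
        inversions = diffs > curve.sd_rmse_mm[1:]
        assert inversions.sum() <= 1
        assert (abs(curve.mean_rmse_mm[-1] - curve.in_sample_reference_mm)
                < 3 * max(curve.sd_rmse_mm[-1], 1e-6))
        # out-of-sample error lower-bounded by in-sample accuracy
        assert curve.mean_rmse_mm[-1] >= (curve.in_sample_reference_mm
                                          - 2 * curve.sd_rmse_mm[-1])


class TestDetectConvergence:
    def _curve(self, sizes, means):
        return GeneralizationCurve(training_sizes=sizes, mean_rmse_mm=means,
                                   sd_rmse_mm=np.zeros(len(sizes)),
                                   repetitions=1, in_sample_reference_mm=0.0)

    def test_constant_curve_converges_immediately(self):
        curve = self._curve([10, 20, 30, 40], np.full(4, 0.5))
        assert detect_convergence(curve) == 10

    def test_analytic_hyperbolic_curve(self):
        # c(s) = a + b/s: per-sample improvement b/(s_j s_{j-1}) crosses the
        # threshold at a size computable in closed form from the grid
        a, b = 0.3, 40.0
        sizes = np.array([10, 20, 40, 80, 160, 320, 640])
        means = a + b / sizes
        smooth = np.convolve(np.pad(means, 1, mode="edge"), np.ones(3) / 3,
                             mode="valid")
        imp = -np.diff(smooth) / np.diff(sizes)
        expected = None
        for j in range(len(sizes)):
            if np.all(imp[j:] < 1e-3):
                expected = sizes[j]
                break
        got = detect_convergence(self._curve(sizes, means), threshold_mm=1e-3)
        assert got == expected
        assert got is not None

    def test_never_converging_curve_returns_none(self):
        sizes = np.array([10, 20, 30, 40])
        means = np.array([10.0, 8.0, 6.0, 4.0])  # keeps improving fast
        assert detect_convergence(self._curve(sizes, means), 1e-3) is None


class TestSpecificity:
    def test_zero_variance_model_is_fully_specific(self, rng):
        row = rng.normal(size=12)
        training = _aligned_set(np.tile(row, (5, 1)))
        model = build_model(training)
        spec = specificity(model, training, model.n_modes, n_samples=20, rng=0)
        assert spec.mean <= 1e-8

    def test_matches_brute_force_nearest_neighbor(self, rng):
        X = rng.normal(size=(3, 12)) * 4
        training = _aligned_set(X)
        model = build_model(training)
        from osteomorph.model import sample_coefficients

        spec = specificity(model, training, model.n_modes, n_samples=100, rng=9)
        B = sample_coefficients(model, model.n_modes, rng=9, size=100)
        samples = model.mean_shape + B @ model.eigenvectors.T
        mins = []
        for s in samples:  # exhaustive double loop
            best = min(np.sqrt(((s - t) ** 2).sum() / 4) for t in X)
            mins.append(best)
        assert spec.mean == pytest.approx(np.mean(mins), abs=1e-10)
        assert spec.sd == pytest.approx(np.std(mins), abs=1e-10)

    def test_denser_training_is_more_specific(self, rng):
        # same generator, more training shapes -> smaller specificity
        gen = np.random.default_rng(31)
        U = np.linalg.qr(gen.normal(size=(30, 2)))[0]

        def sample_set(n):
            b = gen.normal(size=(n, 2)) * np.sqrt([16.0, 4.0])
            return _aligned_set(b @ U.T)

        sparse = sample_set(10)
        dense = sample_set(200)
        m_sparse = build_model(sparse)
        m_dense = build_model(dense)
        s_sparse = specificity(m_sparse, sparse, 2, n_samples=500, rng=1)
        s_dense = specificity(m_dense, dense, 2, n_samples=500, rng=1)
        assert s_dense.mean <= s_sparse.mean + 2 * s_sparse.sd / np.sqrt(500)


class TestRigidMotionInvariance:
    def test_metrics_invariant_to_global_motion(self, rng):
        X = rng.normal(size=(8, 15)) * 6 + 40
        configs = [LandmarkConfiguration(subject_id=str(i), structure="toy",
                                         points=X[i].reshape(-1, 3))
                   for i in range(8)]
        Q = random_rotation(rng)
        moved = [c.with_points(c.points @ Q.T + np.array([12.0, -3.0, 7.0]))
                 for c in configs]

        def metrics(cfgs):
            aligned = generalized_procrustes(cfgs, tol=1e-10)
            model = build_model(aligned)
            return (
                accuracy(model, aligned, 2).mean,
                compactness(model),
                size_dominance(model),
                specificity(model, aligned, 2, n_samples=50, rng=4).mean,
            )

        a0, c0, s0, sp0 = metrics(configs)
        a1, c1, s1, sp1 = metrics(moved)
        assert a0 == pytest.approx(a1, abs=1e-6)
        np.testing.assert_allclose(c0, c1, atol=1e-8)
        assert s0 == pytest.approx(s1, abs=1e-8)
        assert sp0 == pytest.approx(sp1, abs=1e-6)
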