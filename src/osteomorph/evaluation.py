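"""Goodness metrics for statistical shape models.

Implements the four standard SSM quality measures on corresponded landmarks —
in-sample accuracy, compactness, leave-one-out generalization and specificity
— plus size dominance, the generalization-versus-training-size experiment and
the convergence rule that estimates the training size needed for population
coverage. All RMSE values are per-shape root-mean-square distances between
corresponding points, in mm, reported as mean +/- sd over shapes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
from scipy.spatial.distance import cdist

from .geometry import AlignedShapeSet, generalized_procrustes, unflatten
from .model import (
    ShapeModel,
    build_model,
    modes_for_variance,
    project,
    reconstruct,
    sample_coefficients,
)

__all__ = [
    "MeanSd",
    "EvaluationReport",
    "GeneralizationCurve",
    "ModesForAccuracy",
    "accuracy",
    "modes_for_accuracy",
    "compactness",
    "size_dominance",
    "projection_fitter",
    "generalization_loo",
    "generalization_curve",
    "detect_convergence",
    "specificity",
    "evaluate_model",
]


@dataclass(frozen=True)
class MeanSd:
    """A mean +/- sd pair (mm)."""

    mean: float
    sd: float

    def __iter__(self):
        yield self.mean
        yield self.sd

    def __format__(self, spec):  # "1.23 +/- 0.08"-style table entries
        spec = spec or ".2f"
        return f"{self.mean:{spec}} +/- {self.sd:{spec}}"


@dataclass
class ModesForAccuracy:
    """Outcome of the joint accuracy/variance mode-count rule."""

    M: int
    accuracy: MeanSd
    variance_fraction: float
    reached: bool


@dataclass
class EvaluationReport:
    """Table-style evaluation record for one structure."""

    structure: str
    n_train: int
    M_used: int
    variance_fraction: float
    size_dominance: float
    accuracy_mm: MeanSd
    compactness: np.ndarray
    specificity_mm: Optional[MeanSd] = None
    generalization_mm: Optional[MeanSd] = None

    def to_dict(self) -> dict:
        d = {
            "structure": self.structure,
            "n_train": self.n_train,
            "M_used": self.M_used,
            "variance_fraction": self.variance_fraction,
            "size_dominance": self.size_dominance,
            "accuracy_mean_mm": self.accuracy_mm.mean,
            "accuracy_sd_mm": self.accuracy_mm.sd,
            "compactness": list(map(float, self.compactness)),
        }
        if self.specificity_mm is not None:
            d["specificity_mean_mm"] = self.specificity_mm.mean
            d["specificity_sd_mm"] = self.specificity_mm.sd
        if self.generalization_mm is not None:
            d["generalization_mean_mm"] = self.generalization_mm.mean
            d["generalization_sd_mm"] = self.generalization_mm.sd
        return d


@dataclass
class GeneralizationCurve:
    """Generalization RMSE as a function of training-set size."""

    training_sizes: np.ndarray
    mean_rmse_mm: np.ndarray
    sd_rmse_mm: np.ndarray
    repetitions: int
    in_sample_reference_mm: float

    def __post_init__(self) -> None:
        self.training_sizes = np.asarray(self.training_sizes, dtype=int)
        self.mean_rmse_mm = np.asarray(self.mean_rmse_mm, dtype=float)
        self.sd_rmse_mm = np.asarray(self.sd_rmse_mm, dtype=float)
        if not (self.training_sizes.size == self.mean_rmse_mm.size == self.sd_rmse_mm.size):
            raise ValueError("curve vectors must share length")
        if np.any(np.diff(self.training_sizes) <= 0):
            raise ValueError("training_sizes must be strictly increasing")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "training_size": self.training_sizes,
                "mean_rmse_mm": self.mean_rmse_mm,
                "sd_rmse_mm": self.sd_rmse_mm,
            }
        )

    def plot(self, ax=None):
        """Error-bar plot of the curve with the in-sample reference line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.errorbar(self.training_sizes, self.mean_rmse_mm, yerr=self.sd_rmse_mm,
                    marker="o", capsize=3, label="generalization RMSE")
        ax.axhline(self.in_sample_reference_mm, linestyle=":", color="k",
                   label="in-sample accuracy")
        ax.set_xlabel("training shapes")
        ax.set_ylabel("RMSE (mm)")
        ax.legend()
        return ax


def _per_shape_rmse(diff: np.ndarray) -> np.ndarray:
    """Per-row RMSE over corresponding points of flattened difference rows."""
    diff = np.atleast_2d(diff)
    K = diff.shape[1] // 3
    return np.sqrt((diff**2).sum(axis=1) / K)


def accuracy(model: ShapeModel, training: AlignedShapeSet, M: int) -> MeanSd:
    """In-sample reconstruction accuracy with M modes (mean +/- sd RMSE, mm).

    Each training shape is projected onto the first M eigenmodes and the RMSE
    of corresponding-point distances between reconstruction and original is
    averaged over the sample. M = 0 degenerates to the RMSD to the mean shape.
    """
    if M < 0 or M > model.n_modes:
        raise IndexError(f"M={M} out of range [0, {model.n_modes}]")
    Xc = training.shapes - model.mean_shape
    if M == 0:
        resid = Xc
    else:
        P = model.eigenvectors[:, :M]
        resid = Xc - (Xc @ P) @ P.T
    rmse = _per_shape_rmse(resid)
    return MeanSd(float(rmse.mean()), float(rmse.std()))


def modes_for_accuracy(
    model: ShapeModel,
    training: AlignedShapeSet,
    target_mm: float,
    min_variance: float = 0.95,
) -> ModesForAccuracy:
    """Smallest M with mean accuracy <= target_mm and cumulative variance >= min_variance.

    If no mode count reaches the accuracy target the full model (M = t) is
    reported with ``reached=False``.
    """
    if not target_mm > 0:
        raise ValueError("target_mm must be positive")
    comp = compactness(model) if model.n_modes else np.array([])
    M_start = modes_for_variance(model, min_variance) if model.n_modes else 0
    for M in range(M_start, model.n_modes + 1):
        acc = accuracy(model, training, M)
        if acc.mean <= target_mm:
            frac = float(comp[M - 1]) if M > 0 else 0.0
            return ModesForAccuracy(M=M, accuracy=acc, variance_fraction=frac, reached=True)
    acc = accuracy(model, training, model.n_modes)
    frac = float(comp[-1]) if model.n_modes else 0.0
    return ModesForAccuracy(M=model.n_modes, accuracy=acc, variance_fraction=frac,
                            reached=acc.mean <= target_mm)


def compactness(model: ShapeModel) -> np.ndarray:
    """Cumulative explained-variance fractions of the eigenmode spectrum."""
    if model.n_modes == 0:
        raise ValueError("model has no modes")
    return np.cumsum(model.eigenvalues) / model.total_variance


def size_dominance(model: ShapeModel) -> float:
    """Fraction of total variance carried by the first principal component."""
    if model.n_modes == 0:
        raise ValueError("model has no modes")
    return float(model.eigenvalues[0] / model.total_variance)


@dataclass
class FitOutcome:
    """What a fitter returns: weights, the pose it found, and the fit RMSE."""

    coefficients: np.ndarray
    rmse_mm: float


def projection_fitter(model: ShapeModel, target_points: np.ndarray, M: int,
                      n_iter: int = 3) -> FitOutcome:
    """Fit a fully corresponded target by alternating alignment and projection.

    The target is rigidly aligned to the current reconstruction (starting at
    the mean shape) and projected onto the first M modes; a few alternations
    suffice because correspondences are known. This is the fast fitter used in
    leave-one-out experiments; :func:`osteomorph.fitting.fit_unseen` is the
    robust ICP alternative for unlabeled or outlier-bearing targets.
    """
    from .geometry import _umeyama, flatten

    pts = unflatten(target_points)
    recon = model.mean_points()
    b = np.zeros(M)
    for _ in range(max(1, n_iter)):
        R, t, s = _umeyama(pts, recon, allow_scale=False)
        aligned = s * pts @ R.T + t
        b = project(model, flatten(aligned), M).b
        recon = unflatten(reconstruct(model, b))
    rmse = float(np.sqrt(((aligned - recon) ** 2).sum() / pts.shape[0]))
    return FitOutcome(coefficients=b, rmse_mm=rmse)


def _resolve_rule(model: ShapeModel, M_rule: Union[int, float]) -> int:
    if isinstance(M_rule, (int, np.integer)) and not isinstance(M_rule, bool):
        return min(int(M_rule), model.n_modes)
    return modes_for_variance(model, float(M_rule))


def generalization_loo(
    dataset: AlignedShapeSet,
    M_rule: Union[int, float] = 0.95,
    fitter: Callable = projection_fitter,
    gpa_tol: float = 1e-7,
) -> MeanSd:
    """Leave-one-out generalization error (mean +/- sd RMSE, mm).

    For every shape i a model is built on the remaining n - 1 shapes —
    re-running the Procrustes superimposition on the subset, so no alignment
    information leaks from the held-out shape — and the held-out shape is
    fitted with ``fitter``. ``M_rule`` is either a fixed mode count (int) or a
    variance fraction (float). Fitter failures are recorded and the fold is
    excluded; the failure count is reported in a warning.
    """
    n = dataset.n_shapes
    if n < 3:
        raise ValueError("leave-one-out needs n >= 3")
    errors = []
    failures = []
    for i in range(n):
        rest = [j for j in range(n) if j != i]
        try:
            subset = generalized_procrustes(
                dataset.subset_configurations(rest),
                allow_scale=dataset.scaled, tol=gpa_tol,
            )
            fold_model = build_model(subset)
            M = _resolve_rule(fold_model, M_rule)
            outcome = fitter(fold_model, unflatten(dataset.shapes[i]), M)
            errors.append(outcome.rmse_mm)
        except Exception as exc:  # noqa: BLE001 - fold failures are data, not bugs
            failures.append((i, repr(exc)))
    if failures:
        warnings.warn(
            f"{len(failures)} of {n} leave-one-out folds failed and were excluded: "
            f"{failures[:3]}",
            RuntimeWarning,
        )
    if not errors:
        raise RuntimeError("all leave-one-out folds failed")
    arr = np.asarray(errors)
    return MeanSd(float(arr.mean()), float(arr.std()))


def generalization_curve(
    dataset: AlignedShapeSet,
    sizes: Sequence[int],
    repetitions: int = 20,
    rng=None,
    M_rule: Union[int, float] = 0.95,
    fitter: Callable = projection_fitter,
    gpa_tol: float = 1e-7,
) -> GeneralizationCurve:
    """Generalization error versus number of training shapes.

    For each size s, ``repetitions`` times: draw a random held-out target and
    s random non-target shapes, re-align, build a model and fit the target.
    The in-sample reference is the full-sample accuracy at the same mode rule.
    Reproducible for a fixed seed.
    """
    sizes = np.asarray(list(sizes), dtype=int)
    if np.any(np.diff(sizes) <= 0):
        raise ValueError("sizes must be strictly increasing")
    n = dataset.n_shapes
    if sizes.max() > n - 1:
        raise ValueError(f"max size {sizes.max()} exceeds n-1 = {n - 1}")
    if sizes.min() < 2:
        raise ValueError("smallest training size must be >= 2")
    rng = np.random.default_rng(rng)

    means = np.empty(sizes.size)
    sds = np.empty(sizes.size)
    for k, s in enumerate(sizes):
        errs = np.empty(repetitions)
        for r in range(repetitions):
            target = int(rng.integers(n))
            pool = np.array([j for j in range(n) if j != target])
            chosen = rng.choice(pool, size=int(s), replace=False)
            subset = generalized_procrustes(
                dataset.subset_configurations(chosen),
                allow_scale=dataset.scaled, tol=gpa_tol,
            )
            fold_model = build_model(subset)
            M = _resolve_rule(fold_model, M_rule)
            errs[r] = fitter(fold_model, unflatten(dataset.shapes[target]), M).rmse_mm
        means[k] = errs.mean()
        sds[k] = errs.std()

    full_model = build_model(dataset)
    reference = accuracy(full_model, dataset, _resolve_rule(full_model, M_rule)).mean
    return GeneralizationCurve(
        training_sizes=sizes,
        mean_rmse_mm=means,
        sd_rmse_mm=sds,
        repetitions=repetitions,
        in_sample_reference_mm=reference,
    )


def detect_convergence(curve: GeneralizationCurve, threshold_mm: float = 1e-3):
    """Training size after which the curve stops improving.

    The mean curve is smoothed with a 3-point moving average (raw Monte-Carlo
    curves are noisy), successive improvements are normalized per added
    training sample, and the result is the smallest tabulated size after
    which every later improvement stays below ``threshold_mm`` (default
    1e-3 mm per sample). Returns ``None`` when never satisfied.
    """
    if curve.training_sizes.size < 3:
        raise ValueError("convergence detection needs >= 3 curve points")
    y = curve.mean_rmse_mm
    smooth = np.convolve(np.pad(y, 1, mode="edge"), np.ones(3) / 3, mode="valid")
    steps = np.diff(curve.training_sizes)
    improvement = -np.diff(smooth) / steps  # mm gained per added sample
    below = improvement < threshold_mm
    # smallest size s_j with every later improvement below threshold; the last
    # size has no successor and cannot witness convergence by itself
    for j in range(curve.training_sizes.size - 1):
        if np.all(below[j:]):
            return int(curve.training_sizes[j])
    return None


def specificity(
    model: ShapeModel,
    training: AlignedShapeSet,
    M: int,
    n_samples: int = 10_000,
    rng=None,
    truncation_sd: float = 3.0,
) -> MeanSd:
    """Distance from model-sampled shapes to their nearest training member.

    Generates ``n_samples`` (default 10,000) random shape instances from the
    truncated-normal mode distribution and records, for each, the RMSE to the
    closest training shape over corresponding points (mean +/- sd, mm). Small
    values mean the model only generates realistic shapes.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    K = model.n_landmarks
    B = sample_coefficients(model, M, rng, truncation_sd, size=n_samples)
    samples = model.mean_shape + B @ model.eigenvectors[:, :M].T
    # chunked nearest-neighbor scan keeps memory bounded for large n_samples
    mins = np.empty(n_samples)
    chunk = max(1, int(2e7 // max(training.shapes.shape[0], 1)))
    for start in range(0, n_samples, chunk):
        d = cdist(samples[start:start + chunk], training.shapes)
        mins[start:start + chunk] = d.min(axis=1)
    rmse = mins / np.sqrt(K)
    return MeanSd(float(rmse.mean()), float(rmse.std()))


def evaluate_model(
    results_or_model,
    training: Optional[AlignedShapeSet] = None,
    variance_target: float = 0.95,
    accuracy_target_mm: float = 0.6,
    specificity_samples: int = 10_000,
    truncation_sd: float = 3.0,
    rng=None,
    generalization: bool = False,
    M_rule: Optional[Union[int, float]] = None,
) -> EvaluationReport:
    """Assemble the per-structure evaluation table.

    The reported mode count follows the joint rule: enough modes for the
    accuracy target (default 0.6 mm) while covering at least the variance
    target (default 95%).
    """
    from .model import ShapeModelResults

    if isinstance(results_or_model, ShapeModelResults):
        model = results_or_model.model
        training = training or results_or_model.training
    else:
        model = results_or_model
    if training is None:
        raise ValueError("evaluation needs the training sample")

    rule = modes_for_accuracy(model, training, accuracy_target_mm, variance_target)
    spec = specificity(model, training, rule.M, n_samples=specificity_samples,
                       rng=rng, truncation_sd=truncation_sd)
    gen = None
    if generalization:
        gen = generalization_loo(training, M_rule if M_rule is not None else variance_target)
    return EvaluationReport(
        structure=model.structure,
        n_train=model.n_train,
        M_used=rule.M,
        variance_fraction=rule.variance_fraction,
        size_dominance=size_dominance(model),
        accuracy_mm=rule.accuracy,
        compactness=compactness(model),
        specificity_mm=spec,
        generalization_mm=gen,
    )
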