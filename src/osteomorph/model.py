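"""PCA point-distribution models: S = S_bar + P b.

A statistical shape model represents every member of a corresponded landmark
population as the mean shape plus a weighted sum of orthonormal eigenmodes of
the sample covariance. The decomposition is computed from the thin SVD of the
centered data matrix (never the explicit 3K x 3K covariance, which can be
large for dense quasi-landmark sets); eigenvalues use the n - 1 normalization,
which scales the spectrum but not any variance-fraction quantity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy.stats import truncnorm

from .geometry import AlignedShapeSet, flatten, unflatten

__all__ = [
    "InsufficientDataError",
    "ShapeModel",
    "ShapeCoefficients",
    "build_model",
    "reconstruct",
    "project",
    "sample_shape",
    "sample_coefficients",
    "modes_for_variance",
    "PointDistributionModel",
    "ShapeModelResults",
]

#: relative eigenvalue cutoff below which a mode is treated as null
NULL_MODE_RTOL = 1e-12

_FORMAT_VERSION = 1


class InsufficientDataError(ValueError):
    """Too few training shapes to estimate a covariance."""


@dataclass
class ShapeModel:
    """Mean shape, eigenmode matrix and eigenvalue spectrum of an SSM.

    ``eigenvectors`` has orthonormal columns (3K x t); ``eigenvalues`` are the
    per-mode variances in mm^2, sorted descending, with at most n_train - 1
    retained modes.
    """

    mean_shape: np.ndarray
    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    n_train: int
    scaled: bool = False
    structure: str = ""
    layout: str = "xyz-interleaved"
    version: int = _FORMAT_VERSION

    def __post_init__(self) -> None:
        self.mean_shape = np.asarray(self.mean_shape, dtype=float).reshape(-1)
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float).reshape(-1)
        if self.eigenvectors.ndim != 2:
            raise ValueError("eigenvectors must be a (3K, t) matrix")
        if self.eigenvectors.shape[0] != self.mean_shape.size:
            raise ValueError("eigenvector rows must match mean_shape length")
        if self.eigenvectors.shape[1] != self.eigenvalues.size:
            raise ValueError("eigenvalue count must match eigenvector columns")
        if np.any(self.eigenvalues < -1e-10):
            raise ValueError("eigenvalues must be nonnegative")
        self.eigenvalues = np.clip(self.eigenvalues, 0.0, None)
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be sorted descending")

    @property
    def n_modes(self) -> int:
        return self.eigenvalues.size

    @property
    def n_landmarks(self) -> int:
        return self.mean_shape.size // 3

    @property
    def total_variance(self) -> float:
        return float(self.eigenvalues.sum())

    def mean_points(self) -> np.ndarray:
        return unflatten(self.mean_shape)

    def save(self, path) -> None:
        """Serialize to a single ``.npz`` container (bit-faithful arrays)."""
        meta = json.dumps(
            {
                "n_train": int(self.n_train),
                "scaled": bool(self.scaled),
                "structure": self.structure,
                "layout": self.layout,
                "version": int(self.version),
            }
        )
        np.savez(
            path,
            mean_shape=self.mean_shape,
            eigenvectors=self.eigenvectors,
            eigenvalues=self.eigenvalues,
            meta=np.array(meta),
        )

    @classmethod
    def load(cls, path) -> "ShapeModel":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            return cls(
                mean_shape=data["mean_shape"],
                eigenvectors=data["eigenvectors"],
                eigenvalues=data["eigenvalues"],
                n_train=meta["n_train"],
                scaled=meta["scaled"],
                structure=meta["structure"],
                layout=meta["layout"],
                version=meta["version"],
            )


@dataclass
class ShapeCoefficients:
    """Mode weights b_1..b_M of a shape expressed in a model's eigenbasis."""

    b: np.ndarray
    M: int = -1

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=float).reshape(-1)
        if self.M < 0:
            self.M = self.b.size
        if self.M != self.b.size:
            raise ValueError("M must equal len(b)")


def build_model(aligned: Union[AlignedShapeSet, np.ndarray], structure: str = "",
                scaled: Optional[bool] = None) -> ShapeModel:
    """Eigen-decompose the sample covariance of an aligned shape sample.

    Modes with eigenvalues below ``NULL_MODE_RTOL`` times the leading
    eigenvalue are treated as numerical null space and dropped, so a sample of
    identical shapes yields a model with zero modes.
    """
    if isinstance(aligned, AlignedShapeSet):
        X = aligned.shapes
        structure = structure or aligned.structure
        scaled = aligned.scaled if scaled is None else scaled
    else:
        X = np.asarray(aligned, dtype=float)
        scaled = bool(scaled)
    if X.ndim != 2 or X.shape[0] < 2:
        raise InsufficientDataError("building a model needs n >= 2 aligned shapes")
    n = X.shape[0]
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    lam = s**2 / (n - 1)
    lam = lam[: n - 1]
    Vt = Vt[: n - 1]
    if lam.size and lam[0] > 0:
        keep = lam >= NULL_MODE_RTOL * lam[0]
    else:
        keep = np.zeros(lam.size, dtype=bool)
    lam = lam[keep]
    P = Vt[keep].T
    # deterministic sign: largest-magnitude loading of each mode is positive
    for j in range(P.shape[1]):
        i = np.argmax(np.abs(P[:, j]))
        if P[i, j] < 0:
            P[:, j] = -P[:, j]
    return ShapeModel(
        mean_shape=mean,
        eigenvectors=P,
        eigenvalues=lam,
        n_train=n,
        scaled=bool(scaled),
        structure=structure,
    )


def _resolve_M(model: ShapeModel, M: Optional[int]) -> int:
    if M is None:
        return model.n_modes
    M = int(M)
    if M < 0 or M > model.n_modes:
        raise IndexError(f"M={M} out of range [0, {model.n_modes}]")
    return M


def reconstruct(model: ShapeModel, coeffs: Union[ShapeCoefficients, np.ndarray]) -> np.ndarray:
    """Return ``S_bar + sum_m P_m b_m`` as a flattened 3K vector."""
    b = coeffs.b if isinstance(coeffs, ShapeCoefficients) else np.asarray(coeffs, dtype=float)
    M = b.size
    if M > model.n_modes:
        raise IndexError(f"{M} coefficients exceed the model's {model.n_modes} modes")
    if M == 0:
        return model.mean_shape.copy()
    return model.mean_shape + model.eigenvectors[:, :M] @ b


def project(model: ShapeModel, shape: np.ndarray, M: Optional[int] = None) -> ShapeCoefficients:
    """Least-squares mode weights ``b_m = p_m^T (S - S_bar)`` for m <= M.

    ``shape`` must already sit in the model frame; by orthonormality of the
    eigenmodes the projection is the optimal M-mode reconstruction.
    """
    M = _resolve_M(model, M)
    vec = flatten(shape)
    if vec.size != model.mean_shape.size:
        raise ValueError("shape length does not match the model")
    b = model.eigenvectors[:, :M].T @ (vec - model.mean_shape)
    return ShapeCoefficients(b=b, M=M)


def sample_coefficients(
    model: ShapeModel,
    M: Optional[int],
    rng,
    truncation_sd: float = 3.0,
    size: Optional[int] = None,
) -> np.ndarray:
    """Draw mode weights b_m ~ N(0, lambda_m) truncated at +-truncation_sd sd.

    ``rng`` is a seed or ``numpy.random.Generator``; the coefficient stream is
    bit-reproducible for a fixed seed. ``truncation_sd = 0`` degenerates to
    the mean shape (all-zero weights); negative values are invalid.
    """
    if truncation_sd < 0:
        raise ValueError("truncation_sd must be >= 0")
    M = _resolve_M(model, M)
    rng = np.random.default_rng(rng)
    shape = (M,) if size is None else (size, M)
    if truncation_sd == 0 or M == 0:
        return np.zeros(shape)
    sd = np.sqrt(model.eigenvalues[:M])
    draws = truncnorm.rvs(-truncation_sd, truncation_sd, size=shape, random_state=rng)
    return draws * sd


def sample_shape(
    model: ShapeModel,
    M: Optional[int] = None,
    rng=None,
    truncation_sd: float = 3.0,
):
    """Sample one random shape instance; returns ``(coefficients, 3K vector)``."""
    b = sample_coefficients(model, M, rng, truncation_sd)
    coeffs = ShapeCoefficients(b=b)
    return coeffs, reconstruct(model, coeffs)


def modes_for_variance(model: ShapeModel, fraction: float) -> int:
    """Smallest M whose cumulative eigenvalue fraction reaches ``fraction``."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if model.n_modes == 0:
        return 0
    cum = np.cumsum(model.eigenvalues) / model.total_variance
    # 1e-12 guard so exact boundaries (e.g. 3/4 with spectrum (3,1)) use >=
    return int(np.searchsorted(cum, fraction - 1e-12) + 1)


class PointDistributionModel:
    """Point-distribution model of a Procrustes-aligned landmark sample.

    Statsmodels-style model object: construct from data, then :meth:`fit`
    computes the eigen-decomposition and returns :class:`ShapeModelResults`.

    Parameters
    ----------
    data : AlignedShapeSet or (n, 3K) ndarray
        Superimposed training sample (rows are flattened shape vectors).
    structure : str, optional
        Anatomical structure name carried into reports.
    """

    def __init__(self, data, structure: str = "", scaled: Optional[bool] = None):
        if isinstance(data, AlignedShapeSet):
            self.aligned = data
        else:
            X = np.asarray(data, dtype=float)
            self.aligned = AlignedShapeSet(
                shapes=X,
                mean_shape=X.mean(axis=0),
                transforms=None,
                scaled=bool(scaled),
                structure=structure,
            )
        self.structure = structure or self.aligned.structure
        self._scaled = self.aligned.scaled if scaled is None else scaled

    @classmethod
    def from_configurations(cls, configs, allow_scale: bool = False,
                            tol: float = 1e-7, max_iter: int = 100):
        """Run generalized Procrustes alignment, then wrap the result."""
        from .geometry import generalized_procrustes

        aligned = generalized_procrustes(configs, allow_scale=allow_scale,
                                         tol=tol, max_iter=max_iter)
        return cls(aligned)

    def fit(self) -> "ShapeModelResults":
        model = build_model(self.aligned, structure=self.structure, scaled=self._scaled)
        return ShapeModelResults(model=model, training=self.aligned)


@dataclass
class ShapeModelResults:
    """Fitted PCA shape model plus the training sample it came from.

    Carries the estimates (mean, eigenmodes, spectrum) and exposes the
    reconstruction/projection/sampling operations and the goodness metrics.
    """

    model: ShapeModel
    training: Optional[AlignedShapeSet] = None

    # -- thin delegations -------------------------------------------------
    def reconstruct(self, coeffs) -> np.ndarray:
        return reconstruct(self.model, coeffs)

    def project(self, shape, M: Optional[int] = None) -> ShapeCoefficients:
        return project(self.model, shape, M)

    def sample_shape(self, M: Optional[int] = None, rng=None, truncation_sd: float = 3.0):
        return sample_shape(self.model, M, rng, truncation_sd)

    def modes_for_variance(self, fraction: float) -> int:
        return modes_for_variance(self.model, fraction)

    def training_coefficients(self, M: Optional[int] = None) -> np.ndarray:
        """Mode weights of every training row, as an (n, M) matrix."""
        if self.training is None:
            raise ValueError("results carry no training sample")
        M = _resolve_M(self.model, M)
        return (self.training.shapes - self.model.mean_shape) @ self.model.eigenvectors[:, :M]

    # -- goodness metrics (delegated to the evaluation module) ------------
    def compactness(self) -> np.ndarray:
        from .evaluation import compactness

        return compactness(self.model)

    def size_dominance(self) -> float:
        from .evaluation import size_dominance

        return size_dominance(self.model)

    def accuracy(self, M: Optional[int] = None):
        from .evaluation import accuracy

        return accuracy(self.model, self.training, _resolve_M(self.model, M))

    def specificity(self, M: Optional[int] = None, n_samples: int = 10_000,
                    rng=None, truncation_sd: float = 3.0):
        from .evaluation import specificity

        return specificity(self.model, self.training, _resolve_M(self.model, M),
                           n_samples=n_samples, rng=rng, truncation_sd=truncation_sd)

    def save(self, path) -> None:
        self.model.save(path)

    def summary(self, variance_target: float = 0.95,
                accuracy_target_mm: float = 0.6) -> str:
        """Plain-text summary table of the fitted model."""
        m = self.model
        lines = [
            "Point-Distribution Model Results",
            "=" * 44,
            f"{'structure':<28}{m.structure or '-'}",
            f"{'training shapes (n)':<28}{m.n_train}",
            f"{'landmarks (K)':<28}{m.n_landmarks}",
            f"{'retained modes (t)':<28}{m.n_modes}",
            f"{'scale removed':<28}{m.scaled}",
            f"{'total variance (mm^2)':<28}{m.total_variance:.4f}",
        ]
        if m.n_modes:
            lines.append(f"{'size dominance (PC1, %)':<28}{100 * self.size_dominance():.2f}")
            M95 = self.modes_for_variance(variance_target)
            lines.append(
                f"{'modes for ' + format(100 * variance_target, '.0f') + '% variance':<28}{M95}"
            )
            if self.training is not None:
                from .evaluation import modes_for_accuracy

                res = modes_for_accuracy(self.model, self.training,
                                         accuracy_target_mm, variance_target)
                lines.append(
                    f"{'modes for ' + format(accuracy_target_mm, '.2f') + ' mm':<28}"
                    f"{res.M}{'' if res.reached else ' (target unreachable)'}"
                )
                lines.append(
                    f"{'accuracy at that M (mm)':<28}"
                    f"{res.accuracy.mean:.4f} +/- {res.accuracy.sd:.4f}"
                )
        lines.append("=" * 44)
        return "\n".join(lines)
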