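"""Landmark configurations, similarity transforms and Procrustes superimposition.

Conventions used throughout the package:

* landmark configurations are ordered ``(K, 3)`` arrays in millimetres, with
  homology by index (point ``i`` is the same anatomical location in every
  configuration of a structure);
* flattened shape vectors interleave coordinates as ``x1, y1, z1, x2, ...``;
* the coordinate frame is right-handed with ``x`` the lateral axis, so the
  sagittal mirror negates ``x``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "CorrespondenceError",
    "DegenerateGeometryError",
    "LandmarkConfiguration",
    "SimilarityTransform",
    "AlignedShapeSet",
    "flatten",
    "unflatten",
    "centroid_size",
    "align_pair",
    "generalized_procrustes",
    "procrustes_distance",
    "reflect",
]

SIDES = ("left", "right", "none")
SEXES = ("male", "female", "unknown")


class CorrespondenceError(ValueError):
    """Point counts or orderings of two configurations are incompatible."""


class DegenerateGeometryError(ValueError):
    """Configuration is collinear or coincident; the alignment is not unique."""


def flatten(points: np.ndarray) -> np.ndarray:
    """Flatten a ``(K, 3)`` array to the interleaved ``3K`` layout."""
    return np.asarray(points, dtype=float).reshape(-1)


def unflatten(vector: np.ndarray) -> np.ndarray:
    """Inverse of :func:`flatten`."""
    return np.asarray(vector, dtype=float).reshape(-1, 3)


def centroid_size(points: np.ndarray) -> float:
    """Root summed squared distance of the landmarks to their centroid (mm)."""
    pts = unflatten(points)
    centred = pts - pts.mean(axis=0)
    return float(np.sqrt((centred**2).sum()))


@dataclass(frozen=True)
class LandmarkConfiguration:
    """One bone instance: an ordered 3D point set plus subject metadata."""

    subject_id: str
    structure: str
    points: np.ndarray
    side: str = "none"
    sex: str = "unknown"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must be (K, 3); got {pts.shape}")
        if pts.shape[0] < 4:
            raise ValueError("a configuration needs at least 4 landmarks")
        if not np.all(np.isfinite(pts)):
            raise ValueError("landmark coordinates must be finite")
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}")
        object.__setattr__(self, "points", pts)

    @property
    def n_landmarks(self) -> int:
        return self.points.shape[0]

    def centroid_size(self) -> float:
        return centroid_size(self.points)

    def with_points(self, points: np.ndarray) -> "LandmarkConfiguration":
        return replace(self, points=np.asarray(points, dtype=float))


@dataclass(frozen=True)
class SimilarityTransform:
    """``x -> scale * R @ x + t`` with a proper rotation ``R``."""

    rotation: np.ndarray
    translation: np.ndarray
    scale: float = 1.0

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det +1)")
        if not self.scale > 0:
            raise ValueError("scale must be positive")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        object.__setattr__(self, "scale", float(self.scale))

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(np.eye(3), np.zeros(3), 1.0)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = unflatten(points)
        return self.scale * pts @ self.rotation.T + self.translation

    def compose(self, inner: "SimilarityTransform") -> "SimilarityTransform":
        """Return the transform equivalent to applying ``inner`` first, then self."""
        return SimilarityTransform(
            rotation=self.rotation @ inner.rotation,
            translation=self.scale * self.rotation @ inner.translation + self.translation,
            scale=self.scale * inner.scale,
        )

    def inverse(self) -> "SimilarityTransform":
        Rinv = self.rotation.T
        return SimilarityTransform(
            rotation=Rinv,
            translation=-Rinv @ self.translation / self.scale,
            scale=1.0 / self.scale,
        )


@dataclass
class AlignedShapeSet:
    """A Procrustes-superimposed sample: one flattened shape vector per row."""

    shapes: np.ndarray
    mean_shape: np.ndarray
    transforms: Optional[list]
    scaled: bool
    configs: Optional[list] = None
    structure: str = ""

    def __post_init__(self) -> None:
        self.shapes = np.asarray(self.shapes, dtype=float)
        self.mean_shape = np.asarray(self.mean_shape, dtype=float)
        if self.shapes.ndim != 2:
            raise ValueError("shapes must be an (n, 3K) matrix")
        if self.mean_shape.shape != (self.shapes.shape[1],):
            raise ValueError("mean_shape length must match shape rows")

    @property
    def n_shapes(self) -> int:
        return self.shapes.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.shapes.shape[1] // 3

    @property
    def subject_ids(self) -> list:
        if self.configs is None:
            return [str(i) for i in range(self.n_shapes)]
        return [c.subject_id for c in self.configs]

    @property
    def sex_labels(self) -> list:
        if self.configs is None:
            return ["unknown"] * self.n_shapes
        return [c.sex for c in self.configs]

    def row_configuration(self, i: int) -> LandmarkConfiguration:
        """The i-th aligned row wrapped back into a configuration."""
        meta = self.configs[i] if self.configs is not None else None
        return LandmarkConfiguration(
            subject_id=meta.subject_id if meta else str(i),
            structure=meta.structure if meta else self.structure,
            points=unflatten(self.shapes[i]),
            side=meta.side if meta else "none",
            sex=meta.sex if meta else "unknown",
        )

    def subset_configurations(self, indices: Sequence[int]) -> list:
        return [self.row_configuration(int(i)) for i in indices]


def _check_nondegenerate(points: np.ndarray) -> None:
    centred = points - points.mean(axis=0)
    s = np.linalg.svd(centred, compute_uv=False)
    if s[0] <= 0 or s[1] <= 1e-10 * s[0]:
        raise DegenerateGeometryError(
            "configuration is (near-)collinear or coincident; alignment is not unique"
        )


def _umeyama(source: np.ndarray, target: np.ndarray, allow_scale: bool):
    """Closed-form least-squares similarity transform source -> target."""
    mx = source.mean(axis=0)
    my = target.mean(axis=0)
    Xc = source - mx
    Yc = target - my
    H = Xc.T @ Yc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.array([1.0, 1.0, d])
    R = Vt.T @ (D[:, None] * U.T)
    if allow_scale:
        scale = float((S * D).sum() / (Xc**2).sum())
    else:
        scale = 1.0
    t = my - scale * R @ mx
    return R, t, scale


def align_pair(
    source: LandmarkConfiguration,
    target: LandmarkConfiguration,
    allow_scale: bool = False,
):
    """Least-squares (Procrustes) superimposition of ``source`` onto ``target``.

    Returns the minimizing :class:`SimilarityTransform` and the transformed
    source configuration. With ``allow_scale=False`` only translation and
    rotation are removed, preserving centroid size.
    """
    if source.n_landmarks != target.n_landmarks:
        raise CorrespondenceError(
            f"point counts differ: {source.n_landmarks} vs {target.n_landmarks}"
        )
    _check_nondegenerate(source.points)
    _check_nondegenerate(target.points)
    R, t, s = _umeyama(source.points, target.points, allow_scale)
    transform = SimilarityTransform(R, t, s)
    return transform, source.with_points(transform.apply(source.points))


def procrustes_distance(a, b, allow_scale: bool = False) -> float:
    """Root-mean-square landmark distance after optimal superimposition."""
    pa = unflatten(a)
    pb = unflatten(b)
    if pa.shape != pb.shape:
        raise CorrespondenceError("configurations must share K")
    R, t, s = _umeyama(pa, pb, allow_scale)
    diff = (s * pa @ R.T + t) - pb
    return float(np.sqrt((diff**2).sum() / pa.shape[0]))


def _principal_axis_rotation(points: np.ndarray) -> np.ndarray:
    """Rotation taking a centred configuration to its principal axes.

    The sign of each axis is fixed by the third moment of the projected
    coordinates (falling back to the largest-magnitude coordinate), so the
    gauge is reproducible across runs and input orderings.
    """
    centred = points - points.mean(axis=0)
    _, _, Vt = np.linalg.svd(centred, full_matrices=False)
    V = Vt.T
    for j in range(2):
        proj = centred @ V[:, j]
        skew = (proj**3).sum()
        if abs(skew) > 1e-9:
            sgn = np.sign(skew)
        else:
            sgn = np.sign(proj[np.argmax(np.abs(proj))])
            sgn = sgn if sgn != 0 else 1.0
        V[:, j] *= sgn
    V[:, 2] = np.cross(V[:, 0], V[:, 1])
    return V


def generalized_procrustes(
    dataset: Sequence[LandmarkConfiguration],
    allow_scale: bool = False,
    tol: float = 1e-7,
    max_iter: int = 100,
) -> AlignedShapeSet:
    """Generalized Procrustes analysis against an evolving mean shape.

    Iterates pairwise superimposition onto the current mean until the RMS
    change of the mean drops below ``tol`` (mm) or ``max_iter`` is reached
    (non-convergence emits a warning, not an error). After convergence the
    mean is rotated to its principal axes so serialized models are comparable
    across runs, and every *original* configuration is aligned once more to
    that fixed mean to produce the stored rows and transforms.
    """
    configs = list(dataset)
    if len(configs) < 2:
        raise ValueError("generalized Procrustes needs at least 2 configurations")
    K = configs[0].n_landmarks
    for c in configs:
        if c.n_landmarks != K:
            raise CorrespondenceError(
                f"configuration {c.subject_id}/{c.side} has K={c.n_landmarks}, expected {K}"
            )
    point_sets = [c.points for c in configs]

    mean = point_sets[0] - point_sets[0].mean(axis=0)
    if allow_scale:
        mean = mean / centroid_size(mean)
    converged = False
    delta = np.inf
    for _ in range(max_iter):
        aligned = []
        for pts in point_sets:
            R, t, s = _umeyama(pts, mean, allow_scale)
            aligned.append(s * pts @ R.T + t)
        new_mean = np.mean(aligned, axis=0)
        new_mean = new_mean - new_mean.mean(axis=0)
        if allow_scale:
            new_mean = new_mean / centroid_size(new_mean)
        delta = float(np.sqrt(((new_mean - mean) ** 2).mean()))
        mean = new_mean
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"generalized Procrustes did not converge in {max_iter} iterations "
            f"(final mean RMS change {delta:.3e} mm)",
            RuntimeWarning,
        )

    mean = mean @ _principal_axis_rotation(mean)

    transforms = []
    rows = np.empty((len(configs), 3 * K))
    for i, pts in enumerate(point_sets):
        R, t, s = _umeyama(pts, mean, allow_scale)
        transform = SimilarityTransform(R, t, s)
        transforms.append(transform)
        rows[i] = flatten(transform.apply(pts))

    return AlignedShapeSet(
        shapes=rows,
        mean_shape=rows.mean(axis=0),
        transforms=transforms,
        scaled=allow_scale,
        configs=configs,
        structure=configs[0].structure,
    )


def reflect(
    config: LandmarkConfiguration,
    relabel_map: Optional[np.ndarray] = None,
) -> LandmarkConfiguration:
    """Sagittal mirror (negate x) followed by landmark relabeling.

    ``relabel_map`` must be a bijection on the landmark indices pairing each
    landmark with its mirror-homologous partner (identity by default). With an
    involutive map, applying :func:`reflect` twice returns the input exactly.
    The metadata ``side`` flips left/right.
    """
    K = config.n_landmarks
    if relabel_map is None:
        relabel = np.arange(K)
    else:
        relabel = np.asarray(relabel_map, dtype=int)
        if relabel.shape != (K,) or not np.array_equal(np.sort(relabel), np.arange(K)):
            raise ValueError("relabel_map must be a bijection on 0..K-1")
    mirrored = config.points * np.array([-1.0, 1.0, 1.0])
    new_side = {"left": "right", "right": "left"}.get(config.side, config.side)
    return replace(config, points=mirrored[relabel], side=new_side)
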