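"""Bilateral (matching) symmetry decomposition and asymmetry analysis.

Left/right bone pairs are separate structures, so matching symmetry applies:
the left configuration is mirrored and relabeled to the right side's landmark
ordering, the pair is jointly Procrustes-superimposed (without scaling), and
each side decomposes exactly into the pair's consensus — its bilaterally
symmetric part — plus an asymmetry residual. The residuals of the two sides
are coordinate-wise negatives of each other, so population-level asymmetry is
analyzed from one residual vector per subject (using both would double-count
anti-symmetric copies).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .geometry import (
    AlignedShapeSet,
    CorrespondenceError,
    LandmarkConfiguration,
    generalized_procrustes,
    reflect,
    unflatten,
)
from .model import ShapeModel

__all__ = [
    "SymmetryDecomposition",
    "symmetric_consensus",
    "decompose_population",
    "asymmetry_pca",
    "mean_asymmetry_map",
    "asymmetry_sex_variance",
]


@dataclass
class SymmetryDecomposition:
    """Symmetric consensus plus per-side asymmetry residuals for one subject.

    ``consensus + residual_left`` reproduces the aligned (mirrored) left side
    exactly, ``consensus + residual_right`` the aligned right side;
    ``per_vertex_mm`` holds the per-landmark residual magnitudes.
    """

    subject_id: str
    consensus: np.ndarray
    residual_left: np.ndarray
    residual_right: np.ndarray
    per_vertex_mm: np.ndarray
    sex: str = "unknown"


def _decomposition(subject_id, sex, row_left, row_right) -> SymmetryDecomposition:
    consensus = 0.5 * (row_left + row_right)
    residual_left = row_left - consensus
    residual_right = row_right - consensus
    per_vertex = np.linalg.norm(unflatten(residual_right), axis=1)
    return SymmetryDecomposition(
        subject_id=subject_id,
        consensus=consensus,
        residual_left=residual_left,
        residual_right=residual_right,
        per_vertex_mm=per_vertex,
        sex=sex,
    )


def symmetric_consensus(
    left: LandmarkConfiguration,
    right: LandmarkConfiguration,
    relabel_map: Optional[np.ndarray] = None,
) -> SymmetryDecomposition:
    """Decompose one left/right pair into consensus and asymmetry residuals.

    The left side is mirrored and relabeled, the pair is superimposed by a
    two-configuration Procrustes analysis (no scaling), and the consensus is
    the arithmetic mean of the aligned pair, making the two residuals exact
    coordinate-wise negatives.
    """
    if left.n_landmarks != right.n_landmarks:
        raise CorrespondenceError(
            f"left K={left.n_landmarks} vs right K={right.n_landmarks}"
        )
    mirrored = reflect(left, relabel_map)
    aligned = generalized_procrustes([mirrored, right], allow_scale=False, tol=1e-10)
    return _decomposition(right.subject_id, right.sex,
                          aligned.shapes[0], aligned.shapes[1])


def decompose_population(
    pairs: Sequence,
    relabel_map: Optional[np.ndarray] = None,
    tol: float = 1e-7,
):
    """Joint symmetry decomposition of a population of left/right pairs.

    All mirrored-left and right configurations (2n in total) are superimposed
    in a single generalized Procrustes analysis so that consensus shapes and
    residuals of different subjects live in one common frame — required for
    any across-subject statistic. Returns ``(decompositions, consensus_set)``
    where ``consensus_set`` is an :class:`AlignedShapeSet` of the n consensus
    shapes (the sample the shape model is built from).
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no subjects")
    configs = []
    for left, right in pairs:
        if left.n_landmarks != right.n_landmarks:
            raise CorrespondenceError(
                f"subject {right.subject_id}: left K={left.n_landmarks} "
                f"vs right K={right.n_landmarks}"
            )
        configs.append(reflect(left, relabel_map))
        configs.append(right)
    aligned = generalized_procrustes(configs, allow_scale=False, tol=tol)

    decomps = []
    consensus_rows = np.empty((len(pairs), aligned.shapes.shape[1]))
    consensus_configs = []
    for i, (left, right) in enumerate(pairs):
        d = _decomposition(right.subject_id, right.sex,
                           aligned.shapes[2 * i], aligned.shapes[2 * i + 1])
        decomps.append(d)
        consensus_rows[i] = d.consensus
        consensus_configs.append(
            LandmarkConfiguration(
                subject_id=right.subject_id,
                structure=right.structure,
                points=unflatten(d.consensus),
                side="none",
                sex=right.sex,
            )
        )
    consensus_set = AlignedShapeSet(
        shapes=consensus_rows,
        mean_shape=consensus_rows.mean(axis=0),
        transforms=None,
        scaled=False,
        configs=consensus_configs,
        structure=pairs[0][1].structure,
    )
    return decomps, consensus_set


def _stack_residuals(decompositions: Sequence[SymmetryDecomposition]) -> np.ndarray:
    return np.vstack([d.residual_right for d in decompositions])


def asymmetry_pca(
    decompositions: Sequence[SymmetryDecomposition],
    center: bool = False,
) -> ShapeModel:
    """PCA of the asymmetry residual fields (one residual vector per subject).

    By default the population-mean residual (directional asymmetry) is *not*
    subtracted, so the leading mode mixes directional and fluctuating
    asymmetry; pass ``center=True`` to analyze fluctuating asymmetry alone.
    """
    decompositions = list(decompositions)
    if len(decompositions) < 2:
        raise ValueError("asymmetry PCA needs >= 2 subjects")
    R = _stack_residuals(decompositions)
    n = R.shape[0]
    mean = R.mean(axis=0) if center else np.zeros(R.shape[1])
    Rc = R - mean
    _, s, Vt = np.linalg.svd(Rc, full_matrices=False)
    lam = s**2 / (n - 1)
    t_max = n - 1 if center else n
    lam = lam[:t_max]
    Vt = Vt[:t_max]
    if lam.size and lam[0] > 0:
        keep = lam >= 1e-12 * lam[0]
    else:
        keep = np.zeros(lam.size, dtype=bool)
    return ShapeModel(
        mean_shape=mean,
        eigenvectors=Vt[keep].T,
        eigenvalues=lam[keep],
        n_train=n,
        scaled=False,
        structure="asymmetry-residuals",
    )


def mean_asymmetry_map(decompositions: Sequence[SymmetryDecomposition]) -> np.ndarray:
    """Per-vertex mean residual magnitude across subjects (mm).

    This is the scalar field projected onto the consensus shape in asymmetry
    heat maps.
    """
    decompositions = list(decompositions)
    if not decompositions:
        raise ValueError("no subjects")
    return np.mean([d.per_vertex_mm for d in decompositions], axis=0)


def asymmetry_sex_variance(
    decompositions: Sequence[SymmetryDecomposition],
    labels: Optional[Sequence] = None,
) -> float:
    """Percent of asymmetry-residual variance explained by sex.

    Uses the same partial-least-squares machinery as the dimorphism module,
    applied to the residual matrix. Labels default to the decompositions' own
    sex metadata.
    """
    from .dimorphism import pls_sex_variance

    decompositions = list(decompositions)
    if labels is None:
        labels = [d.sex for d in decompositions]
    return pls_sex_variance(_stack_residuals(decompositions), labels)
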