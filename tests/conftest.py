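"""Shared fixtures: tiny deterministic shapes and cached synthetic cohorts."""

import numpy as np
import pytest

from osteomorph import (
    PointDistributionModel,
    SyntheticPopulationSpec,
    decompose_population,
    simulate_population,
)


def random_rotation(rng) -> np.ndarray:
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_240_915)


@pytest.fixture
def tetrahedron():
    return np.array(
        [[0.0, 0.0, 0.0], [10.0, 0.0, 0.0], [0.0, 8.0, 0.0], [0.0, 0.0, 6.0]]
    )


@pytest.fixture(scope="session")
def small_population():
    """Noise-free 100-subject cohort without pose, for exact-ish identities."""
    spec = SyntheticPopulationSpec(
        n_subjects=100, n_landmarks=60, noise_sd=0.0,
        asymmetry_amplitude_sd=0.0, random_pose=False, seed=11,
    )
    return simulate_population(spec)


@pytest.fixture(scope="session")
def small_model(small_population):
    dataset, _ = small_population
    decomps, consensus = decompose_population(dataset.pairs, dataset.relabel_map)
    return PointDistributionModel(consensus).fit()


@pytest.fixture(scope="session")
def study_population():
    """Default study conditions at n=400, for parameter-recovery checks."""
    spec = SyntheticPopulationSpec(n_subjects=400, n_landmarks=100, seed=7)
    return simulate_population(spec)


@pytest.fixture(scope="session")
def study_decomposition(study_population):
    dataset, _ = study_population
    return decompose_population(dataset.pairs, dataset.relabel_map)
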