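import numpy as np
import pytest

from morphoconverge.synthetic import SimulationParams, make_template, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260906)


@pytest.fixture(scope="session")
def small_template():
    """k_pairs=3, k_midline=2 symmetric template (k=8)."""
    return make_template(3, 2, seed=11)


@pytest.fixture(scope="session")
def quick_params():
    """Small, fast design for unit tests (balanced cells of 8)."""
    return SimulationParams(
        k_pairs=4,
        k_midline=2,
        n_per_cell=(8, 8, 8, 8, 8, 8),
        lineage_offset=0.08,
        period_shift=0.02,
        convergence=0.0,
        noise_sd=0.02,
        seed=7,
    )


@pytest.fixture(scope="session")
def quick_dataset(quick_params):
    dataset, truth = simulate_dataset(quick_params)
    return dataset, truth


def random_configuration(rng, k=10, scale=1.0):
    return scale * rng.standard_normal((k, 3))


def random_similarity(rng, coords, max_scale=3.0):
    """Apply a random rotation, translation and positive scaling."""
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    s = rng.uniform(0.3, max_scale)
    t = rng.uniform(-10, 10, 3)
    return s * coords @ q + t
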