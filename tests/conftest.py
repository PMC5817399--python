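import numpy as np
import pytest

from morphodisp.geometry import gpa
from morphodisp.synthetic import (
    default_landmark_scheme,
    fish_outline,
    generate_landmark_dataset,
    recovery_design,
)


@pytest.fixture(scope="session")
def base_outline():
    return fish_outline()


@pytest.fixture(scope="session")
def scheme():
    return default_landmark_scheme()


@pytest.fixture(scope="session")
def small_landmark_dataset(scheme):
    """A small planted dataset (10/bin) shared across geometry/pipeline tests."""
    design = recovery_design(10)
    configs, records, truth = generate_landmark_dataset(design, seed=11)
    return design, configs, records, truth


@pytest.fixture(scope="session")
def small_aligned(small_landmark_dataset):
    _, configs, _, _ = small_landmark_dataset
    return gpa(configs)


def random_similarity_copies(base, n, rng):
    """Copies of one shape under random rotation/translation/scaling."""
    out = []
    for _ in range(n):
        theta = rng.uniform(0, 2 * np.pi)
        R = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        out.append(rng.uniform(0.5, 3.0) * (base @ R.T) + rng.uniform(-5, 5, 2))
    return out
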