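import numpy as np
import pytest

import polysol as ps


@pytest.fixture(scope="session")
def small_corpus() -> ps.Dataset:
    """Ten-system noisy corpus for cheap end-to-end checks."""
    return ps.generate_corpus(
        ps.GeneratorConfig(n_systems=10, points_per_system=8, noise_sd=3.0, seed=11)
    )


@pytest.fixture(scope="session")
def default_corpus() -> ps.Dataset:
    """The generator's default study conditions (20 systems x 8 loads)."""
    return ps.generate_corpus(ps.GeneratorConfig())


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_xy(rng):
    """Small random regression problem in the scaled-feature box."""
    X = rng.uniform(0.0, 1.0, size=(6, 3))
    y = 100.0 + 50.0 * X[:, 2] - 20.0 * X[:, 0] + rng.normal(0, 2, 6)
    return X, y
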