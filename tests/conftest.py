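import numpy as np
import pytest

from mixmerge import PosteriorMatrix, posteriors_from_mixture, two_pair_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def two_pair_posteriors():
    """Posteriors and data of the deterministic two-pair demonstration model."""
    params, data, labels = two_pair_fixture()
    return posteriors_from_mixture(params, data), data, labels


@pytest.fixture
def capture_gamma():
    """Three components; the third wins the argmax at every point while the
    first two have identical densities — the fixture separating demp's
    conditional best-in-overlap behavior from demp2's."""
    return np.tile([0.2, 0.2, 0.6], (40, 1))


@pytest.fixture
def hard_gamma():
    """Balanced hard assignment over two components."""
    g = np.zeros((10, 2))
    g[:5, 0] = 1.0
    g[5:, 1] = 1.0
    return g
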