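import numpy as np
import pytest

from metseg import phantom


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_series():
    """A deterministic 2-lesion, 3-session phantom series (shared, read-only)."""
    spec = phantom.PhantomSpec(
        grid_shape=(64, 64, 64),
        n_lesions=2,
        lesion_diameters_mm=(12.0, 8.0),
        trajectory=((1.0, 0.6, 0.4), (1.0, 0.8, 0.0)),
        seed=7,
    )
    return phantom.generate_series(spec)


def ball_mask(shape, center, radius, spacing=(1.0, 1.0, 1.0)):
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    q = sum(((g - c) * s) ** 2 for g, c, s in zip(grids, center, spacing))
    return q <= radius**2


@pytest.fixture()
def ball():
    return ball_mask
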