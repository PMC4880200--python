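import numpy as np
import pytest

from tractdelta.bundle_io import RawBundle, ScalarVolume


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def constant_volume():
    """20 mm cube of FA 0.5 at 1 mm isotropic resolution."""
    return ScalarVolume(data=np.full((20, 20, 20), 0.5), affine=np.eye(4))


@pytest.fixture
def straight_bundle():
    """20 straight fibers from near the origin to near (100, 0, 0) mm."""
    rng = np.random.default_rng(7)
    fibers = []
    for _ in range(20):
        start = rng.normal([0, 0, 0], 0.5)
        end = rng.normal([100, 0, 0], 0.5)
        t = np.linspace(0, 1, 11)[:, None]
        fibers.append(start + t * (end - start))
    return RawBundle(fibers=fibers)


def random_polyline(rng, n_vertices=20, scale=5.0):
    """Smooth-ish random 3D polyline (cumulative small random steps)."""
    steps = rng.normal(0, scale, size=(n_vertices, 3))
    steps[:, 0] = np.abs(steps[:, 0]) + scale  # keep advancing in x
    return np.cumsum(steps, axis=0)
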