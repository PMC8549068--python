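import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_blob_distance_matrix(rng):
    """Distance matrix of two well-separated planar blobs, 20 points each."""
    from scipy.spatial.distance import cdist

    pts = np.vstack(
        [rng.normal(0.0, 1.0, (20, 2)), rng.normal(10.0, 1.0, (20, 2))]
    )
    return cdist(pts, pts), pts
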