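import numpy as np
import pytest


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def three_blobs(rng):
    """Three tight, well-separated isotropic 3-D blobs with ground truth."""
    centers = np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0], [0.0, 10.0, 0.0]])
    pts, labels = [], []
    for k, c in enumerate(centers, start=1):
        pts.append(c + 0.05 * rng.standard_normal((50, 3)))
        labels.extend([k] * 50)
    return np.vstack(pts), np.array(labels), centers


@pytest.fixture(scope="session")
def low_bank():
    from ldadp import make_templates

    return make_templates(3, similarity="low", seed=0)
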