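import numpy as np
import pytest

import wristmorph as wm


@pytest.fixture(scope="session")
def template():
    return wm.make_template()


@pytest.fixture(scope="session")
def template_mesh(template):
    return wm.build_mesh(template, resolution=2.0)


@pytest.fixture(scope="session")
def canonical_frame():
    """Identity frame at the template pose."""
    return wm.AnatomicFrame(origin=np.zeros(3), axes=np.eye(3))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)


def random_triad(rng, spread=15.0):
    """A random non-degenerate landmark triad for property tests."""
    while True:
        pts = rng.uniform(-spread, spread, size=(3, 3))
        area = 0.5 * np.linalg.norm(np.cross(pts[1] - pts[0], pts[2] - pts[0]))
        if (
            area > 1.0
            and abs(pts[1][0] - pts[2][0]) > 0.1
            and abs(pts[0][2] - pts[1][2]) > 0.1
        ):
            return wm.LandmarkTriad(*pts)
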