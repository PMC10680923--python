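import numpy as np
import pytest

from exotwin.kinematics import DeltaGeometry, GoniometerGeometry


@pytest.fixture(scope="session")
def dg() -> DeltaGeometry:
    return DeltaGeometry()


@pytest.fixture(scope="session")
def gg() -> GoniometerGeometry:
    return GoniometerGeometry()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def sample_workspace_positions(rng, n):
    """Random reachable pivot-platform positions in the working volume."""
    xy = rng.uniform(-0.35, 0.35, (n, 2))
    z = rng.uniform(-0.65, -0.35, (n, 1))
    return np.hstack([xy, z])
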