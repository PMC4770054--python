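import numpy as np
import pytest

from nefsurf import TargetSpec, sample_population


@pytest.fixture(scope="session")
def pop_small():
    """200 neurons, 1D - enough for structural checks, fast."""
    return sample_population(200, 1, 60.0, seed=7)


@pytest.fixture(scope="session")
def pop_mid():
    return sample_population(2000, 1, 60.0, seed=11)


@pytest.fixture(scope="session")
def pop_2d():
    return sample_population(1000, 2, 60.0, seed=13)


@pytest.fixture(scope="session")
def identity_target():
    return TargetSpec(lambda z: np.asarray(z, float),
                      lambda z: np.ones_like(np.asarray(z, float)),
                      lambda z: np.zeros_like(np.asarray(z, float)),
                      name="identity")


@pytest.fixture(scope="session")
def sin_target():
    return TargetSpec(
        lambda z: np.sin(2 * np.pi * np.asarray(z, float)),
        lambda z: 2 * np.pi * np.cos(2 * np.pi * np.asarray(z, float)),
        lambda z: -(2 * np.pi) ** 2 * np.sin(2 * np.pi * np.asarray(z, float)),
        name="sin2pix")


@pytest.fixture(scope="session")
def quartic_target():
    z = np.asarray
    return TargetSpec(lambda x: (1 - z(x, float) ** 2) ** 2,
                      lambda x: -4 * z(x, float) * (1 - z(x, float) ** 2),
                      lambda x: 12 * z(x, float) ** 2 - 4,
                      name="quartic_bump")
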