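import numpy as np
import pytest

import sansfit as sf


@pytest.fixture(scope="session", autouse=True)
def _warm_kernels():
    # trigger numba compilation once so individual test timings are honest
    sf.dumbbell_intensity(np.array([0.01, 0.1]), sf.ANKAIC_DUMBBELL,
                          n_alpha=16, n_z=16)
    cloud = sf.sample_points(sf.ANKAIC_DUMBBELL, 50, 0)
    sf.debye_intensity(cloud, np.array([0.01]))


@pytest.fixture(scope="session")
def q_grid():
    return sf.make_q_grid()


@pytest.fixture(scope="session")
def fixtures():
    return sf.fixture_suite(seed=42)
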