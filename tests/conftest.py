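import numpy as np
import pytest

from pdcflow.synthetic import make_spherical_leadfield


@pytest.fixture(scope="session")
def small_leadfield():
    """48 electrodes, 120 solution points; shared by inverse-stage tests."""
    return make_spherical_leadfield(n_electrodes=48, n_solution_points=120, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
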