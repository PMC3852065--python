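import numpy as np
import pytest

from clusternewton import load_scenario, make_affine_problem


@pytest.fixture(scope="session")
def oc():
    return load_scenario("oc")


@pytest.fixture(scope="session")
def bdc():
    return load_scenario("bdc")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_affine():
    """Consistent, noiseless, rank-deficient log-affine problem."""
    return make_affine_problem(n_params=6, n_objectives=3, rank=3, seed=7)


def random_pbpk_vector(space, rng):
    """One log-uniform draw of a full original-scale PBPK parameter vector."""
    z = rng.uniform(space.log_lower, space.log_upper)
    return space.to_original(z)
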