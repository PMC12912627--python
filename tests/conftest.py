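import numpy as np
import pytest

from gmokw.distributions import GMOKWParams, gmokw_rng


@pytest.fixture(scope="session")
def dataset_I():
    from gmokw.datasets import load_fixture

    return load_fixture("dataset_I").sample


@pytest.fixture(scope="session")
def dataset_II():
    from gmokw.datasets import load_fixture

    return load_fixture("dataset_II").sample


@pytest.fixture(scope="session")
def dataset_III():
    from gmokw.datasets import load_fixture

    return load_fixture("dataset_III").sample


@pytest.fixture(scope="session")
def random_params():
    """A reproducible batch of interior GMOKW parameter draws."""
    rng = np.random.default_rng(20240101)
    draws = []
    for _ in range(10):
        draws.append(GMOKWParams(rng.uniform(0.05, 0.95), rng.uniform(0.05, 0.95),
                                 rng.uniform(0.25, 6.0), rng.uniform(0.25, 6.0)))
    return draws


@pytest.fixture(scope="session")
def gmokw_mle_dataset_I(dataset_I):
    """The headline four-parameter fit, shared across acceptance tests."""
    from gmokw.estimators import fit

    return fit(dataset_I, family="gmokw", method="mle")


@pytest.fixture(scope="session")
def case1_sample():
    return gmokw_rng(200, GMOKWParams(0.25, 0.5, 1.2, 1.5), seed=12345)
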