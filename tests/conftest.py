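import numpy as np
import pytest

from onoffcoding.distributions import AsymmetricLaplace, Gaussian, Laplace, Uniform


@pytest.fixture
def laplace():
    return Laplace()


@pytest.fixture
def rng():
    return np.random.default_rng(20191114)


@pytest.fixture(params=["laplace", "asym", "gaussian", "uniform"])
def any_distribution(request):
    return {
        "laplace": Laplace(),
        "asym": AsymmetricLaplace(tau_plus=1.0, tau_minus=2.0),
        "gaussian": Gaussian(),
        "uniform": Uniform(-1.0, 2.0),
    }[request.param]
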