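import numpy as np
import pytest

from hisfkin.schemes import RateParameterSet, build_scheme


@pytest.fixture(scope="session")
def one_step():
    return build_scheme("ONE_STEP")


@pytest.fixture(scope="session")
def induced_fit():
    return build_scheme("INDUCED_FIT")


@pytest.fixture(scope="session")
def ternary():
    return build_scheme("TERNARY")


@pytest.fixture(scope="session")
def if_params():
    # KD1 = 10 uM, closing equilibrium 20:1 toward closed
    return RateParameterSet({"k1": 10.0, "k-1": 100.0, "kconf": 40.0, "k-conf": 2.0})


@pytest.fixture(scope="session")
def ternary_params():
    return RateParameterSet(
        {"k2": 100.0, "k-2": 5000.0, "k3": 100.0, "k-3": 20000.0, "k4": 50.0, "k-4": 12.0}
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
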