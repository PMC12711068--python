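import numpy as np
import pytest

from iwrecords import IWDParams, simulate_records_quantile

# the likelihood deliberately explores extreme parameter regions during
# optimization; over/underflow there is handled, not a test failure
np.seterr(over="ignore", under="ignore", invalid="ignore", divide="ignore")

STD = IWDParams(1.0, 1.0)


@pytest.fixture(scope="session")
def std_params():
    return STD


@pytest.fixture(scope="session")
def records_n20():
    return simulate_records_quantile(20, STD, seed=7)


@pytest.fixture(scope="session")
def records_n50():
    return simulate_records_quantile(50, STD, seed=11)
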