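import warnings

import pytest

from reburn.synthetic import SimConfig, simulate_campaign
from reburn.vegetation import AllometricTable


@pytest.fixture(scope="session")
def small_campaign():
    """A small (4-fire, ~24-site) campaign shared across read-only tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds, truth = simulate_campaign(SimConfig(n_fires=4), seed=7)
    return ds, truth


@pytest.fixture(scope="session")
def allometry():
    return AllometricTable.default()
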