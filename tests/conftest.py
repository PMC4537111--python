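import numpy as np
import pytest

from guildsim import ForagingParams, GridSpec, ResourceParams


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def grid3():
    return GridSpec(n_rows=3, n_cols=3, toroidal=True)


@pytest.fixture
def grid3_bounded():
    return GridSpec(n_rows=3, n_cols=3, toroidal=False)


@pytest.fixture
def baseline_resources():
    return ResourceParams()


@pytest.fixture
def baseline_foraging():
    return ForagingParams()
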