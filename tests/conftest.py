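import numpy as np
import pytest

import ceusdro as cd


@pytest.fixture(scope="session")
def small_spec():
    return cd.fixture_spec("small")


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    """One small phantom at the default (optimal) acquisition, with truth."""
    stack, truth = cd.synthesize(small_spec, cd.AcquisitionSettings(), seed=7)
    return stack, truth


@pytest.fixture(scope="session")
def vessel_roi(small_spec):
    return cd.vessel_roi_mask(small_spec)


@pytest.fixture
def default_params():
    return cd.LDRWParams(m=1.0, Q=1.0, lam=2.0, mu=30.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
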