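import warnings

import numpy as np
import pytest

from gafdyn.datamodel import SegmentDefinition, SpectrometerConfig
from gafdyn.structure import build_ideal_helix


@pytest.fixture(scope="session")
def cfg():
    return SpectrometerConfig()


@pytest.fixture(scope="session")
def helix20():
    return build_ideal_helix(20)


@pytest.fixture(scope="session")
def segment20():
    return SegmentDefinition("H1", 1, 20, "helix")


@pytest.fixture(autouse=True)
def _quiet_frame_warnings():
    """Terminal-residue exclusion warnings are expected throughout."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*no residue i\\+1.*")
        warnings.filterwarnings("ignore", message=".*excluded with warning.*")
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(0)
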