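import numpy as np
import pytest

from organrheo.profiles import ORGANS, get_profile


@pytest.fixture(params=ORGANS)
def organ_profile(request):
    """Each of the four organ profiles in turn."""
    return get_profile(request.param)


@pytest.fixture
def kidney():
    return get_profile("kidney")


@pytest.fixture
def rng():
    return np.random.default_rng(20240801)
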