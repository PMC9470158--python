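import numpy as np
import pytest
from hypothesis import settings

from fragmodes import FragmentationPattern, ModelParameters

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def lc(request):
    return FragmentationPattern.from_string(request.param)


def P(text: str) -> FragmentationPattern:
    return FragmentationPattern.from_string(text)


@pytest.fixture
def unicellular():
    return P("1+1")


@pytest.fixture
def golden_params():
    """b=(1, 0.5), d=0, all-ones kernel: the standard worked example in
    which the unicellular life cycle has the larger raw growth rate."""
    return ModelParameters([1.0, 0.5], [0.0, 0.0], np.ones((2, 2)))
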