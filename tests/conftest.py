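import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from lmfd import DescriptorParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(params=[DescriptorParams(r=3, kz=1), DescriptorParams(r=5, kz=3)],
                ids=["r3kz1", "r5kz3"])
def preset(request):
    """The two standard descriptor presets."""
    return request.param
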