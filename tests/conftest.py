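import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pcrbias import ContrastBasis

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def basis3() -> ContrastBasis:
    """The three-leaf caterpillar ((A,B),C)."""
    return ContrastBasis.from_tree("((A,B),C);")


@pytest.fixture
def basis4() -> ContrastBasis:
    """The balanced four-leaf tree ((A,B),(C,D))."""
    return ContrastBasis.from_tree("((A,B),(C,D));")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
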