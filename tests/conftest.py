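import numpy as np
import pytest

from bombusdeb import DebParams, build_grid


@pytest.fixture
def params():
    return DebParams()


@pytest.fixture
def grid5():
    """5x5 lattice at 1.2 km spacing with the nest at the central node."""
    return build_grid(5, 1.2, nest_at_center=True)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
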