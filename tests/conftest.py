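import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from shapesearch.profiles import ProfileDatabase, ReactivityProfile


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_profile():
    return ReactivityProfile(
        id="toy",
        sequence="ACGUACGUAC",
        reactivity=np.array([0.1, 0.9, 0.0, 1.2, np.nan, 0.5, 0.3, 0.8, 0.2, 0.6]),
    )


@pytest.fixture
def toy_db(toy_profile):
    other = ReactivityProfile(
        id="other",
        sequence="GGGCCCAAAU",
        reactivity=np.linspace(0.0, 0.9, 10),
    )
    return ProfileDatabase(entries=[toy_profile, other])


def make_profile(rng, length, prefix="p"):
    """Quick structured random profile for tests that just need a signal."""
    from shapesearch.synthetic import random_profile

    return random_profile(length, rng, prefix=prefix)
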