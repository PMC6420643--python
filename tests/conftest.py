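import numpy as np
import pytest

from deamtrace import fixtures


@pytest.fixture(scope="session")
def default_fixture():
    """Seeded synthetic bundle shared by calling/io tests."""
    return fixtures.generate_fixture(fixtures.FixtureSpec(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
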