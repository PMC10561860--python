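import numpy as np
import pytest

from premir import StackingBackend, generate_fixtures


@pytest.fixture(scope="session")
def small_fixtures():
    """20 synthetic records (10 hairpins, 10 negatives) with structures."""
    return generate_fixtures(10, 10, seed=42)


@pytest.fixture(scope="session")
def medium_fixtures():
    """100/100 synthetic study set shared by the slower learning tests."""
    return generate_fixtures(100, 100, seed=7)


@pytest.fixture(scope="session")
def stacking_backend():
    return StackingBackend()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
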