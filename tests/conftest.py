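import pytest

from racemap import random_reference


@pytest.fixture(scope="session")
def model():
    """700-nt synthetic reference with the default window and classes."""
    return random_reference(700, seed=11)


@pytest.fixture(scope="session")
def model750():
    """Longer reference leaving room 3′ of the window ceiling."""
    return random_reference(750, seed=17)
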