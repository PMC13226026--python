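import numpy as np
import pytest

from placentapd import default_config


@pytest.fixture(scope="session")
def cfg():
    """Packaged default study configuration (immutable; shared across tests)."""
    return default_config()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
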