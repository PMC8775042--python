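import numpy as np
import pytest

from cecgclean import SyntheticConfig, generate_cecg
from cecgclean.synthetic import CoarseParams, SlowParams


@pytest.fixture(scope="session")
def short_record():
    """A 60 s default-style record with one of each artifact type — cheap
    enough to share across tests."""
    cfg = SyntheticConfig(
        duration=60.0,
        coarse=CoarseParams(count=2),
        slow=SlowParams(count=1),
        seed=7,
    )
    return generate_cecg(cfg)


@pytest.fixture(scope="session")
def quiet_record():
    """A 60 s record with no injected artifacts."""
    cfg = SyntheticConfig(
        duration=60.0,
        ecg_amp=0.3,
        coarse=CoarseParams(count=0),
        slow=SlowParams(count=0),
        seed=11,
    )
    return generate_cecg(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
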