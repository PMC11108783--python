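import numpy as np
import pytest

from ictaloop import synthgen


@pytest.fixture
def short_config():
    """120 s LFP session with a few seizures, fast to generate."""
    return synthgen.GenConfig(
        duration=120.0, seed=7, seizure_rate=0.05, seizure_min_gap=15.0
    )


@pytest.fixture
def short_session(short_config):
    return synthgen.generate_lfp(short_config)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
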