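import numpy as np
import pytest

from rootmir import SimulationConfig, make_reference


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=7, n_families=10, n_transcripts=15,
                            transcript_length=1000, n_target_sites=5)


@pytest.fixture(scope="session")
def reference_bundle(small_config):
    """(reference, transcripts, truth) shared across read-level tests."""
    return make_reference(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
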