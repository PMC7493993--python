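import numpy as np
import pytest

from rhizoflow.synthetic_data import SynthConfig, Transcript, generate_transcripts


@pytest.fixture(scope="session")
def default_config():
    return SynthConfig(seed=11)


@pytest.fixture(scope="session")
def synthetic_study(default_config):
    """One full synthetic transcript set with truth, shared across tests."""
    return generate_transcripts(default_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_transcript(rng, length, tid="t"):
    return Transcript(tid, "".join("ACGT"[i] for i in rng.integers(0, 4, size=length)))
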