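import numpy as np
import pytest
from hypothesis import settings

import hipporpe as hp

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def stimulus_set():
    return hp.build_type3_structure()


@pytest.fixture(scope="session")
def small_ensembles():
    """Reduced 12-batch ensembles shared by module-level network tests."""
    early = hp.run_batches("early", 12, 910_000)
    delayed = hp.run_batches("delayed", 12, 920_000)
    return {"early": early, "delayed": delayed}


@pytest.fixture(scope="session")
def directional_ensembles():
    """50-batch-per-condition ensembles for the directional replication
    checks (the scale at which the qualitative effects are assessed)."""
    early = hp.run_batches("early", 50, 10_000)
    delayed = hp.run_batches("delayed", 50, 20_000)
    return {"early": early, "delayed": delayed}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
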