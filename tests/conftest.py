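import numpy as np
import pytest

from mitocomp.io import load_dussumieri
from mitocomp.simulate import (RepeatPlan, canonical_config, dussumieri_config,
                               generate_mitogenome)


@pytest.fixture(scope="session")
def dussumieri():
    return load_dussumieri()


@pytest.fixture(scope="session")
def sim_canonical():
    """Canonical synthetic genome with a planted 131 bp x 2.4 CR repeat."""
    return generate_mitogenome(canonical_config(seed=11, repeat=RepeatPlan()))


@pytest.fixture(scope="session")
def sim_dussumieri():
    """Synthetic genome mirroring the packaged coordinate fixture's plan."""
    return generate_mitogenome(dussumieri_config(seed=12))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
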