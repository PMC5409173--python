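import numpy as np
import pytest

from frocdwi.signal_models import AcquisitionScheme


@pytest.fixture(scope="session")
def scheme() -> AcquisitionScheme:
    """The four-point breast protocol used throughout."""
    return AcquisitionScheme.breast_protocol()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)
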