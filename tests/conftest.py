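import numpy as np
import pytest

from alpskit import paper_scheme


@pytest.fixture(scope="session")
def gtab():
    """The study acquisition: 1 b0 + 56 directions at b=1000 and b=2000."""
    return paper_scheme()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240722)
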