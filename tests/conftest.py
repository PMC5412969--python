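import numpy as np
import pytest

from tempseg.cohort import default_paper_config


@pytest.fixture(scope="session")
def paper_config():
    """Calibrated default cohort config (computed once per session)."""
    return default_paper_config()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
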