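import numpy as np
import pytest

from meaburst import AnalysisConfig, mcs_8x8


@pytest.fixture(scope="session")
def layout():
    return mcs_8x8()


@pytest.fixture()
def cfg():
    return AnalysisConfig()


@pytest.fixture()
def fast_cfg():
    """Reduced shuffle budget for tests that build whole distance matrices."""
    return AnalysisConfig(n_shuffles=60, shuffle_control_repeats=10)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
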