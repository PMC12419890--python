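import numpy as np
import pytest

from cutmech.core_model import (
    JAPANESE_LAUREL,
    PDMS_4_TO_1,
    PDMS_10_TO_1,
    CutModelConfig,
)


@pytest.fixture
def model_config() -> CutModelConfig:
    return CutModelConfig()


@pytest.fixture
def pdms_4() :
    return PDMS_4_TO_1


@pytest.fixture
def pdms_10():
    return PDMS_10_TO_1


@pytest.fixture
def laurel():
    return JAPANESE_LAUREL


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20250928)
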