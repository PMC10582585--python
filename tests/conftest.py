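import numpy as np
import pytest

from polyqvoc.repeats import HingeConfig


@pytest.fixture
def foxp2_cfg() -> HingeConfig:
    return HingeConfig(gene="FOXP2")


@pytest.fixture
def foxp1_cfg() -> HingeConfig:
    return HingeConfig(gene="FOXP1")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230927)
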