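import numpy as np
import pytest

from pam3p.acoustics import TransducerModel
from pam3p.optics import Chromophore, OpticsConfig


@pytest.fixture
def optics() -> OpticsConfig:
    return OpticsConfig()


@pytest.fixture
def chrom() -> Chromophore:
    return Chromophore()


@pytest.fixture
def transducer() -> TransducerModel:
    return TransducerModel()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
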