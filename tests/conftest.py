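import numpy as np
import pytest

from zoneseg import phantom, preprocess
from zoneseg.model import ModelConfig, ZoneSegNet


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def micro_model():
    """Smallest full network (32x32 input), shared read-only."""
    return ZoneSegNet(ModelConfig.micro(32, seed=7))


@pytest.fixture(scope="session")
def phantom_slices():
    """Foreground-containing benchmark-scale slices from institution A,
    split into (train, val, test)."""
    cfg = phantom.benchmark_config(phantom.INSTITUTION_A, seed=42)
    ds = phantom.generate_institution_dataset(cfg, 5)
    pc = preprocess.PreprocessConfig(crop_ratio=4.0,
                                     target_shape=(10, 32, 32))
    pairs = preprocess.preprocess_dataset(ds, pc)
    fg = [p for p in pairs if (p.mask > 0).any()]
    train = [p for p in fg if p.case_id < 3]
    val = [p for p in fg if p.case_id == 3]
    test = [p for p in fg if p.case_id == 4]
    return train, val, test
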