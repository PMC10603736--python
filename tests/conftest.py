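import numpy as np
import pytest

from aardapt import preprocessing as pp
from aardapt import synthetic as sy


@pytest.fixture(scope="session")
def dog_models():
    return sy.dog_activity_models()


@pytest.fixture(scope="session")
def small_pair(dog_models):
    """A small shifted domain pair with folds assigned (10 windows/class)."""
    cfg = sy.SyntheticConfig(class_models=tuple(dog_models),
                             samples_per_class=10, seed=11)
    source, target = sy.generate_domain_pair(cfg, sy.shift_preset("sensor_position"))
    pp.make_folds(source, seed=0)
    pp.make_folds(target, seed=1)
    return source, target


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
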