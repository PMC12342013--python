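import numpy as np
import pytest

from hemaclone import generate_dataset, make_preset


@pytest.fixture(scope="session")
def small_preset():
    return make_preset("small_test")


@pytest.fixture(scope="session")
def small_dataset(small_preset):
    params, schedule = small_preset
    table, truth = generate_dataset(params, schedule, seed=11)
    return params, schedule, table, truth


@pytest.fixture(scope="session")
def zh33_preset():
    return make_preset("ZH33")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
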