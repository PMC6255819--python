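import numpy as np
import pytest

from mammotex import PhantomParams, build_network, desk_config, generate_phantom


@pytest.fixture(scope="session")
def desk_net():
    return build_network(desk_config())


@pytest.fixture(scope="session")
def cancer_phantom():
    return generate_phantom(PhantomParams(class_label="cancer", height=32, width=32, seed=7))


@pytest.fixture(scope="session")
def normal_phantom():
    return generate_phantom(PhantomParams(class_label="normal", height=32, width=32, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
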