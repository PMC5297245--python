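import pytest

from detbelt import load_detergents


@pytest.fixture(scope="session")
def registry():
    return load_detergents()


@pytest.fixture(scope="session")
def ddm(registry):
    return registry["DDM"]


@pytest.fixture(scope="session")
def ddm_d(registry):
    return registry["DDM-d25"]


@pytest.fixture(scope="session")
def fc12(registry):
    return registry["FC12"]


@pytest.fixture(scope="session")
def fc12_d(registry):
    return registry["FC12-d38"]
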