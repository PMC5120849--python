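from pathlib import Path

import pytest

from moorburn import builtin_sites

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def registry():
    return builtin_sites()


@pytest.fixture(scope="session")
def kerloch(registry):
    return registry["Kerloch"]


@pytest.fixture(scope="session")
def moor_house(registry):
    return registry["Moor House"]


@pytest.fixture(scope="session")
def howden(registry):
    return registry["Howden"]


@pytest.fixture(scope="session")
def dorset(registry):
    return registry["Dorset"]
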