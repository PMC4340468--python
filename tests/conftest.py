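import pytest

from pgxcds import fixtures


@pytest.fixture
def cyp2c9_kb():
    return fixtures.cyp2c9_kb()


@pytest.fixture
def tpmt_kb():
    return fixtures.tpmt_kb()


@pytest.fixture
def demo_kb():
    return fixtures.demo_kb()


@pytest.fixture
def warfarin_patient():
    return fixtures.warfarin_patient()
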