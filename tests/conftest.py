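import pytest

from adescale import load_growth_reference, load_paper_fixtures


@pytest.fixture(scope="session")
def fixtures():
    return load_paper_fixtures()


@pytest.fixture(scope="session")
def growth():
    return load_growth_reference()
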