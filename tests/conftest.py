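import pytest

import therapyrec as tr


@pytest.fixture(scope="session")
def lexicon():
    return tr.default_lexicon()


@pytest.fixture(scope="session")
def example_cat():
    return tr.example_catalog()


@pytest.fixture(scope="session")
def canonical_fixtures():
    return tr.build_canonical_fixtures()
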